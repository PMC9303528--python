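"""Synthetic gene-family generator: planted truth, determinism, recovery."""

import hashlib
import itertools
import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from phylomode import (
    SimulationConfig,
    emit_synthetic_inputs,
    parse_blast_tab,
    simulate_histories,
)
from phylomode.blast import species_of
from phylomode.pipeline import analyze_simulation, cluster_hit_table
from phylomode.simulate import recovery_report


def lossless_config(**kw):
    base = dict(
        seed=42, n_families=50, loss_prob=0.0,
        transcriptome_detection={"CHA": 1.0, "HORN": 1.0, "FERN": 1.0},
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestHistories:
    def test_no_events_gives_full_clade_occupancy(self):
        cfg = lossless_config(
            dup_prob={},
            gain_node_distribution={"Archaeplastida": 1.0},
        )
        res = simulate_histories(cfg)
        tips = cfg.tree.tips
        for h in res.histories:
            assert set(h.surviving_tips) == set(tips)
            assert all(h.occupancy_row[t] != 0 for t in tips)
            assert all(k == 1 for k in h.copy_counts.values())

    def test_forced_duplication_doubles_seed_plant_copies(self):
        cfg = lossless_config(dup_prob={"Spermatophyta": 1.0},
                              gain_node_distribution={"Viridiplantae": 1.0})
        res = simulate_histories(cfg)
        seed_tips = cfg.tree.node("Spermatophyta").tip_set
        for h in res.histories:
            assert h.dup_nodes == ("Spermatophyta",)
            for t in seed_tips:
                assert h.copy_counts[t] == 2

    def test_loss_frequency_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=42, n_families=100, loss_prob=0.1)
        res = simulate_histories(cfg)
        lo, hi = stats.binom.interval(0.99, res.edges_at_risk, 0.1)
        assert lo <= res.n_losses <= hi

    def test_losses_heritable(self):
        # a recorded lost branch never leaves survivors below it
        cfg = SimulationConfig(seed=11, n_families=50, loss_prob=0.3)
        res = simulate_histories(cfg)
        tree = cfg.tree
        for h in res.histories:
            for branch in h.loss_branches:
                node = (tree.node(branch) if branch in tree
                        else tree.nodes[int(branch)])
                assert not (node.tip_set & set(h.surviving_tips))

    def test_gene_tree_consistent_with_occupancy(self):
        cfg = SimulationConfig(seed=5, n_families=60, loss_prob=0.15)
        res = simulate_histories(cfg)
        for h in res.histories:
            detected = {t for t, s in h.occupancy_row.items() if s != 0}
            leaf_species = {species_of(n) for n in h.leaves}
            assert leaf_species == detected or len(h.leaves) < 2

    def test_seed_determinism(self):
        a = simulate_histories(SimulationConfig(seed=7, n_families=30))
        b = simulate_histories(SimulationConfig(seed=7, n_families=30))
        assert [h.gene_tree_newick for h in a.histories] == [
            h.gene_tree_newick for h in b.histories
        ]
        assert [h.occupancy_row for h in a.histories] == [
            h.occupancy_row for h in b.histories
        ]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(loss_prob=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(gain_node_distribution={"Embryophyta": 0.4})
        with pytest.raises(KeyError):
            SimulationConfig(dup_prob={"Atlantis": 0.5})


def _tree_digest(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(path).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestEmit:
    def test_bundle_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_families=20)
        emit_synthetic_inputs(simulate_histories(cfg), tmp_path / "a")
        emit_synthetic_inputs(simulate_histories(cfg), tmp_path / "b")
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")

    def test_zero_noise_components_equal_families(self, tmp_path):
        import networkx as nx

        from phylomode.similarity import build_graph

        cfg = lossless_config(n_families=2, noise_edge_rate=0.0, dup_prob={})
        res = simulate_histories(cfg)
        emit_synthetic_inputs(res, tmp_path)
        hits = parse_blast_tab(tmp_path / "hits.tsv", evalue_cutoff=10.0)
        g = build_graph(hits)
        assert nx.number_connected_components(g) == 2

    def test_noise_edges_poisson_consistent(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_families=40, noise_edge_rate=2.0)
        res = simulate_histories(cfg)
        emit_synthetic_inputs(res, tmp_path)
        hits = parse_blast_tab(tmp_path / "hits.tsv", evalue_cutoff=10.0)
        fam_of = {n: h.family_id for h in res.histories for n in h.leaves}
        cross = {
            frozenset((a.query_id, a.subject_id))
            for a in hits
            if fam_of[a.query_id] != fam_of[a.subject_id]
        }
        lam = cfg.noise_edge_rate * cfg.n_families
        lo, hi = stats.poisson.interval(0.999, lam)
        assert lo <= len(cross) <= hi

    def test_truth_ledger_round_trips(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_families=10)
        res = simulate_histories(cfg)
        emit_synthetic_inputs(res, tmp_path)
        ledger = json.loads((tmp_path / "truth.json").read_text())
        assert set(ledger["families"]) == {h.family_id for h in res.histories}
        for h in res.histories:
            assert ledger["families"][h.family_id]["gain_node"] == h.gain_node


class TestRecovery:
    def test_identity_calls_score_one(self):
        cfg = lossless_config(n_families=30)
        res = simulate_histories(cfg)
        calls = {
            "origins": {h.family_id: h.gain_node for h in res.histories},
            "dup_nodes": {h.family_id: set(h.dup_nodes) for h in res.histories},
        }
        rep = recovery_report(res.histories, calls)
        assert rep["origin_recovery"] == 1.0
        assert rep["dup_recall"] == 1.0 and rep["dup_precision"] == 1.0

    def test_one_wrong_origin_in_ten(self):
        cfg = lossless_config(n_families=10)
        res = simulate_histories(cfg)
        origins = {h.family_id: h.gain_node for h in res.histories}
        origins[res.histories[0].family_id] = "RHO"  # mis-assign one family
        rep = recovery_report(res.histories, {"origins": origins})
        assert rep["origin_recovery"] == pytest.approx(0.9)

    def test_unknown_family_fatal(self):
        res = simulate_histories(lossless_config(n_families=5))
        with pytest.raises(KeyError):
            recovery_report(res.histories, {"origins": {"F9999": "EUD"}})

    def test_lossless_pipeline_recovery_is_exact(self):
        res = simulate_histories(lossless_config(n_families=100))
        rep = recovery_report(res.histories, analyze_simulation(res))
        assert rep["origin_recovery"] == 1.0
        assert rep["dup_recall"] == 1.0
        assert rep["mode_accuracy"] == 1.0

    def test_origin_recovery_degrades_with_loss(self):
        rates = []
        for lp in (0.0, 0.1, 0.25):
            cfg = SimulationConfig(seed=42, n_families=400, loss_prob=lp)
            res = simulate_histories(cfg)
            rep = recovery_report(res.histories, analyze_simulation(res))
            rates.append(rep["origin_recovery"])
        assert rates[0] >= rates[1] >= rates[2]

    def test_clustering_recovers_planted_families(self, tmp_path):
        cfg = SimulationConfig(seed=8, n_families=25, loss_prob=0.1)
        res = simulate_histories(cfg)
        emit_synthetic_inputs(res, tmp_path)
        assign = cluster_hit_table(tmp_path / "hits.tsv")
        rep = recovery_report(res.histories, {"cluster_assignment": assign})
        assert rep["clustering_ari"] == 1.0
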