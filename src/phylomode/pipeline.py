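"""End-to-end glue: run the inference chain over a simulated cohort.

This is the path the recovery benchmarks exercise: occupancy rows go
through single-gain origin inference, gene trees through duplication
mapping, and both feed the mode classifier. Clustering of the emitted hit
tables is optional (it is the slow step and the recovery of origins and
duplications does not depend on it).
"""

from __future__ import annotations

from typing import Mapping

from .blast import parse_blast_tab
from .duplications import load_gene_tree, map_duplications
from .modes import TraitAnnotation, classify_hg
from .origins import infer_origin_node
from .similarity import build_graph, mcl_cluster
from .simulate import (
    SimulationResult,
    default_trait,
    true_mode_labels,
)

__all__ = ["analyze_simulation", "cluster_hit_table"]


def analyze_simulation(
    result: SimulationResult,
    trait: TraitAnnotation | None = None,
    retention_threshold: float = 1.0,
    partial_counts: bool = True,
) -> dict:
    """Infer origins, duplications and mode labels for every family.

    Returns the calls mapping that :func:`phylomode.simulate.recovery_report`
    scores: ``origins``, ``dup_nodes``, ``modes``, ``true_modes``.
    """
    config = result.config
    tree = config.tree
    catalog = config.catalog()
    if trait is None:
        trait = default_trait(config)
    occupancy = result.occupancy()

    origins: dict[str, str | None] = {}
    dup_nodes: dict[str, set[str]] = {}
    modes: dict[str, frozenset[str]] = {}
    true_modes: dict[str, frozenset[str]] = {}
    for history in result.histories:
        fam = history.family_id
        row = occupancy.loc[fam]
        call = infer_origin_node(row, tree, partial_counts=partial_counts, hg_id=fam)
        origins[fam] = call.origin_label if call is not None else None

        events = []
        if history.gene_tree_newick is not None:
            gtree = load_gene_tree(history.gene_tree_newick)
            events = [ev for ev in map_duplications(gtree, tree)]
        dup_nodes[fam] = {ev.mapped_label for ev in events}

        if call is not None:
            mode = classify_hg(
                call, events, trait, row, tree, catalog,
                retention_threshold=retention_threshold,
            )
            modes[fam] = mode.labels
            true_modes[fam] = true_mode_labels(
                history, trait, config, retention_threshold=retention_threshold
            )
    return {
        "origins": origins,
        "dup_nodes": dup_nodes,
        "modes": modes,
        "true_modes": true_modes,
    }


def cluster_hit_table(
    hits_path,
    inflation: float = 2.0,
    evalue_cutoff: float = 1e-5,
) -> Mapping[str, str]:
    """Cluster an emitted hit table; returns protein -> HG id."""
    hits = parse_blast_tab(hits_path, evalue_cutoff=evalue_cutoff)
    graph = build_graph(hits)
    hgs = mcl_cluster(graph, inflation=inflation)
    return {m: hg.hg_id for hg in hgs for m in hg.members}
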