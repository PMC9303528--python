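"""Gene-tree rooting and species-overlap duplication mapping."""

import pytest

from phylomode import SimulationConfig, simulate_histories
from phylomode.duplications import (
    expansions_at_nodes,
    load_gene_tree,
    map_duplications,
    root_by_outgroup,
)
from phylomode.reference import lca_mapping_duplications


def leafsets_of_root(tree):
    return [
        sorted(lf.taxon.label for lf in child.leaf_nodes())
        for child in tree.seed_node.child_nodes()
    ]


class TestRooting:
    def test_single_outgroup_leaf(self, tree):
        g = load_gene_tree("(((EUD|a,MON1|b),CON|c),(RHO|r,FERN|f));")
        rooted = root_by_outgroup(g, tree.outgroup_rank())
        assert ["RHO|r"] in leafsets_of_root(rooted)

    def test_monophyletic_outgroup_clade(self, tree):
        g = load_gene_tree("((CHL|x,CHL|y),(EUD|a,(MON1|b,CON|c)));")
        rooted = root_by_outgroup(g, tree.outgroup_rank())
        assert ["CHL|x", "CHL|y"] in leafsets_of_root(rooted)

    def test_no_outgroup_falls_back_to_midpoint(self, caplog):
        g = load_gene_tree("((EUD|a:1,MON1|b:1):1,(MON2|c:1,AMB|d:5):1);")
        rooted = root_by_outgroup(g, ["RHO", "GLA"])
        assert len(rooted.leaf_nodes()) == 4
        assert any("midpoint" in r.message for r in caplog.records)

    def test_tiny_tree_returned_unchanged(self, caplog):
        g = load_gene_tree("(EUD|a,MON1|b);")
        rooted = root_by_outgroup(g, ["RHO"])
        assert len(rooted.leaf_nodes()) == 2
        assert any("rooting skipped" in r.message for r in caplog.records)

    def test_input_tree_not_mutated(self, tree):
        newick = "(((EUD|a,MON1|b),CON|c),(RHO|r,FERN|f));"
        g = load_gene_tree(newick)
        before = g.as_string(schema="newick")
        root_by_outgroup(g, tree.outgroup_rank())
        assert g.as_string(schema="newick") == before


class TestMapDuplications:
    def test_no_overlap_no_duplications(self, tree):
        g = load_gene_tree("((MOS|a1,EUD|b1),CON|c1);")
        # root is bifurcating; distinct species everywhere -> no events
        assert map_duplications(g, tree) == []

    def test_forced_root_duplication(self, tree):
        g = load_gene_tree("((MOS|a1,EUD|b1),(MOS|a2,EUD|b2));")
        (ev,) = map_duplications(g, tree)
        assert ev.mapped_label == "Embryophyta"
        assert ev.leafset == frozenset(["MOS|a1", "EUD|b1", "MOS|a2", "EUD|b2"])

    def test_single_species_maps_to_terminal_branch(self, tree):
        g = load_gene_tree("((MOS|a1,MOS|a2),EUD|b1);")
        (ev,) = map_duplications(g, tree)
        assert ev.mapped_label == "MOS"

    def test_unrooted_tree_rejected(self, tree):
        g = load_gene_tree("(MOS|a1,EUD|b1,CON|c1);")
        with pytest.raises(ValueError, match="root"):
            map_duplications(g, tree)

    def test_low_support_flagged_but_retained(self, tree):
        g = load_gene_tree("((MOS|a1,EUD|b1)45,(MOS|a2,EUD|b2)99);")
        events = map_duplications(g, tree, min_support=80)
        assert len(events) == 1  # the root event, unlabelled support
        g2 = load_gene_tree("(((MOS|a1,MOS|a2)45,EUD|b1),CON|c1);")
        (ev,) = map_duplications(g2, tree, min_support=80)
        assert ev.low_support and ev.support == 45

    def test_species_subdivision_yields_zero_events(self, tree):
        cfg = SimulationConfig(seed=9, n_families=20, loss_prob=0.2,
                               dup_prob={}, transcriptome_detection={})
        res = simulate_histories(cfg)
        for h in res.histories:
            if h.gene_tree_newick is None:
                continue
            assert map_duplications(load_gene_tree(h.gene_tree_newick), tree) == []

    @pytest.mark.parametrize("seed", [3, 5, 8, 13])
    def test_matches_lca_reconciliation_oracle(self, tree, seed):
        """Species-overlap events equal LCA-mapping events on simulated trees."""
        cfg = SimulationConfig(
            seed=seed, n_families=60, loss_prob=0.15,
            dup_prob={"Embryophyta": 0.25, "Tracheophyta": 0.25, "Spermatophyta": 0.3},
            transcriptome_detection={},
        )
        for h in simulate_histories(cfg).histories:
            if h.gene_tree_newick is None or len(h.leaves) > 16:
                continue
            g = load_gene_tree(h.gene_tree_newick)
            ours = {ev.leafset for ev in map_duplications(g, tree)}
            assert ours == lca_mapping_duplications(g, tree)

    def test_copy_number_forces_log2_duplications(self, tree):
        # a species with k copies needs >= ceil(log2 k) duplications on its
        # root-to-leaf paths; checked on simulated histories
        import math

        cfg = SimulationConfig(
            seed=21, n_families=100, loss_prob=0.0,
            dup_prob={"Spermatophyta": 0.5, "Euphyllophyta": 0.5},
            transcriptome_detection={},
        )
        for h in simulate_histories(cfg).histories:
            if h.gene_tree_newick is None:
                continue
            events = map_duplications(load_gene_tree(h.gene_tree_newick), tree)
            for sp, k in h.copy_counts.items():
                if k > 1:
                    on_path = [
                        ev for ev in events
                        if any(n.startswith(sp + "|") for n in ev.leafset)
                    ]
                    assert len(on_path) >= math.ceil(math.log2(k))


class TestExpansionsAtNodes:
    def test_counts_exact_node_only(self, tree):
        g = load_gene_tree(
            "((CON|a1,(AMB|b1,EUD|c1)),(CON|a2,(AMB|b2,EUD|c2)));"
        )
        events = map_duplications(g, tree)
        counts = expansions_at_nodes(
            events, ["Euphyllophyta", "Spermatophyta"], tree
        )
        assert counts == {"Euphyllophyta": 0, "Spermatophyta": 1}

    def test_double_expansion_separately_counted(self, tree):
        # one event in the ancestor of plants with true leaves, one in the
        # seed-plant ancestor, counted at their own nodes
        g = load_gene_tree(
            "((FERN|f1,(CON|a1,EUD|c1)),(FERN|f2,((CON|a2,EUD|c2),(CON|a3,EUD|c3))));"
        )
        events = map_duplications(g, tree)
        counts = expansions_at_nodes(events, ["Euphyllophyta", "Spermatophyta"], tree)
        assert counts == {"Euphyllophyta": 1, "Spermatophyta": 1}

    def test_no_events_all_zero(self, tree):
        assert expansions_at_nodes([], ["Spermatophyta"], tree) == {"Spermatophyta": 0}

    def test_unknown_label_fatal(self, tree):
        with pytest.raises(KeyError):
            expansions_at_nodes([], ["Atlantis"], tree)
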