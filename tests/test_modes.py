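"""Mode classification, summaries and the packaged worked example."""

import pytest

from phylomode import classify_worked_example, run_worked_example
from phylomode.duplications import DuplicationEvent
from phylomode.modes import (
    ModeCall,
    TraitAnnotation,
    classify_hg,
    emit_heatmap_table,
    summarize_modes,
)
from phylomode.origins import OriginCall


def origin_at(tree, label, hg="HG_X", losses=0):
    node = tree.node(label)
    return OriginCall(
        hg_id=hg, origin=node, origin_label=label,
        implied_losses=losses, presence_tips=frozenset(node.tip_set),
    )


def event_at(tree, label):
    return DuplicationEvent(
        leafset=frozenset(), mapped_node=tree.node(label), mapped_label=label
    )


def full_row(tree, states=2):
    return {t: states for t in tree.tips}


STOMATA = TraitAnnotation(
    "stomata", "Embryophyta", ("Euphyllophyta", "Spermatophyta"), ("EUD|g",)
)
VASCULAR = TraitAnnotation("vascular", "Tracheophyta", ("Spermatophyta",), ("EUD|g",))


class TestClassify:
    def test_origin_at_trait_node_is_novel(self, tree, example):
        call = classify_hg(
            origin_at(tree, "Embryophyta"), [], STOMATA,
            full_row(tree), tree, example.catalog,
        )
        assert call.labels == frozenset({"novel"})

    def test_older_origin_with_full_retention_is_coopted(self, tree, example):
        call = classify_hg(
            origin_at(tree, "Embryophyta"), [], VASCULAR,
            full_row(tree), tree, example.catalog,
        )
        assert call.labels == frozenset({"coopted"})
        assert call.retention_fraction == 1.0

    def test_retention_gap_blocks_cooption(self, tree, example):
        row = full_row(tree)
        row["LYC"] = 0  # one vascular genome species lost
        call = classify_hg(
            origin_at(tree, "Embryophyta"), [], VASCULAR, row, tree, example.catalog
        )
        assert "coopted" not in call.labels
        assert call.retention_fraction < 1.0

    def test_transcriptome_absence_does_not_break_retention(self, tree, example):
        row = full_row(tree)
        row["FERN"] = 1  # partial: transcriptome evidence only
        call = classify_hg(
            origin_at(tree, "Embryophyta"), [], VASCULAR, row, tree, example.catalog
        )
        assert "coopted" in call.labels

    def test_old_origin_with_seed_plant_expansion(self, tree, example):
        # pre-land-plant origin plus a seed-plant duplication
        row = full_row(tree)
        row["LYC"] = 0
        call = classify_hg(
            origin_at(tree, "Viridiplantae"),
            [event_at(tree, "Spermatophyta")],
            STOMATA, row, tree, example.catalog,
        )
        assert call.labels == frozenset({"expanded"})
        assert call.expanded_at == ("Spermatophyta",)

    def test_coopted_and_expanded_combine(self, tree, example):
        call = classify_hg(
            origin_at(tree, "Embryophyta"),
            [event_at(tree, "Spermatophyta")],
            VASCULAR, full_row(tree), tree, example.catalog,
        )
        assert call.labels == frozenset({"coopted", "expanded"})

    def test_younger_origin_reported_post_origin(self, tree, example):
        call = classify_hg(
            origin_at(tree, "Tracheophyta"), [], STOMATA,
            full_row(tree), tree, example.catalog,
        )
        assert call.labels == frozenset({"post_origin"})

    def test_expansion_elsewhere_not_counted(self, tree, example):
        call = classify_hg(
            origin_at(tree, "Embryophyta"), [event_at(tree, "Monocots")],
            STOMATA, full_row(tree), tree, example.catalog,
        )
        assert "expanded" not in call.labels

    def test_novel_coopted_exclusive_invariant(self):
        with pytest.raises(ValueError):
            ModeCall("h", "t", "X", frozenset({"novel", "coopted"}))


class TestSummarize:
    def test_labels_counted_independently(self, tree, example):
        calls = [
            ModeCall("h1", "vascular", "Tracheophyta", frozenset({"novel"})),
            ModeCall("h2", "vascular", "Embryophyta", frozenset({"coopted"})),
            ModeCall("h3", "vascular", "Embryophyta",
                     frozenset({"coopted", "expanded"}),
                     expanded_at=("Spermatophyta",)),
        ]
        out = summarize_modes(calls, [VASCULAR], tree).iloc[0]
        assert (out["novel"], out["coopted"], out["expanded"]) == (1, 2, 1)
        assert out["predates_or_at_origin"] == 3

    def test_empty_trait_gets_zero_row(self, tree, caplog):
        out = summarize_modes([], [VASCULAR], tree)
        assert out.iloc[0]["n_hgs"] == 0
        assert any("no homology groups" in r.message for r in caplog.records)


class TestHeatmap:
    def test_projection_matches_occupancy(self, example):
        gene_map = {g: hg for g, hg in example.gene_to_hg.items()}
        table = emit_heatmap_table(
            example.occupancy, gene_map, example.catalog, example.tree
        )
        assert list(table.columns[2:]) == example.tree.tips
        for gene, hg in gene_map.items():
            for sp in example.tree.tips:
                assert table.at[gene, sp] == example.occupancy.at[hg, sp]
        assert not table["shared_hg"].any()

    def test_shared_hg_rows_repeat_and_flag(self, example):
        gene_map = {"EUD|CPC": "HG_MUTE", "EUD|TRY": "HG_MUTE"}
        table = emit_heatmap_table(
            example.occupancy, gene_map, example.catalog, example.tree
        )
        assert table["shared_hg"].all()
        assert (table.loc["EUD|CPC", example.tree.tips]
                == table.loc["EUD|TRY", example.tree.tips]).all()

    def test_missing_hg_fatal(self, example):
        with pytest.raises(KeyError):
            emit_heatmap_table(
                example.occupancy, {"EUD|x": "HG_NOPE"}, example.catalog, example.tree
            )


class TestWorkedExample:
    def test_expected_classification_ledger(self):
        calls = {(c.trait, c.hg_id): c for c in classify_worked_example()}
        assert calls[("stomatal_development", "HG_MUTE")].labels == {"novel"}
        assert calls[("vascular_tissue", "HG_TMO5")].labels == {"coopted"}
        quac = calls[("stomatal_development", "HG_QUAC1")]
        assert quac.labels == {"expanded"}
        assert quac.expanded_at == ("Spermatophyta",)
        assert calls[("stomatal_development", "HG_STOMAGEN")].labels == {"post_origin"}
        assert calls[("vascular_tissue", "HG_STOMAGEN")].labels == {"novel"}

    def test_origins_and_losses(self):
        calls = {(c.trait, c.hg_id): c for c in classify_worked_example()}
        assert calls[("stomatal_development", "HG_MUTE")].origin_label == "Embryophyta"
        assert calls[("stomatal_development", "HG_MUTE")].implied_losses == 1
        assert calls[("stomatal_development", "HG_QUAC1")].origin_label == "Viridiplantae"
        assert calls[("vascular_tissue", "HG_STOMAGEN")].origin_label == "Tracheophyta"

    def test_outputs_byte_identical(self, tmp_path):
        d1 = run_worked_example(tmp_path / "a")
        d2 = run_worked_example(tmp_path / "b")
        for name in ("modes.tsv", "summary.tsv", "heatmap.tsv", "calls.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
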