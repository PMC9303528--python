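"""Packaged worked example: four archetypal gene families.

A small fully worked fixture on the 14-taxon backbone, one family per mode
of evolution the classifier distinguishes:

* **MUTE-like** — stomatal development gene originating in the land-plant
  ancestor with a liverwort loss: *novel* for a stomatal trait anchored at
  Embryophyta.
* **TMO5-like** — vascular development gene originating in the land-plant
  ancestor, patchy in bryophytes but retained by every vascular-plant
  genome: *coopted* for a vascular trait anchored at Tracheophyta.
* **QUAC1-like** — guard-cell gene originating in the green-plant ancestor
  with a duplication in the seed-plant ancestor: *expanded* at
  Spermatophyta (a lycophyte absence breaks full retention, so no cooption
  call).
* **STOMAGEN-like** — stomatal density regulator originating with vascular
  plants: younger than the stomatal trait (*post_origin*) but *novel* for
  the vascular trait.

Everything is constructed in code; outputs are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .duplications import load_gene_tree, map_duplications
from .modes import ModeCall, TraitAnnotation, classify_hg, emit_heatmap_table, summarize_modes
from .occupancy import SpeciesCatalog, SpeciesInfo, build_occupancy, query_hgs_by_gene_ids
from .origins import infer_origin_node
from .similarity import HomologyGroup
from .species_tree import SpeciesTree, backbone_tree

__all__ = ["WorkedExample", "worked_example", "run_worked_example"]

#: transcriptome-only lineages of the backbone catalog
_TRANSCRIPTOME_TIPS = ("CHA", "HORN", "FERN")

# per-family occupancy (species -> state); omitted species are absent
_FAMILIES: dict[str, dict[str, int]] = {
    "HG_MUTE": {
        "MOS": 2, "HORN": 1, "LYC": 2, "FERN": 1, "CON": 2,
        "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
    "HG_TMO5": {
        "MOS": 2, "LYC": 2, "FERN": 1, "CON": 2,
        "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
    "HG_QUAC1": {
        "CHL": 2, "CHA": 1, "LIV": 2, "MOS": 2, "HORN": 1, "FERN": 1,
        "CON": 2, "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
    "HG_STOMAGEN": {
        "LYC": 2, "FERN": 1, "CON": 2, "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
}

_QUERY_GENES = {
    "HG_MUTE": "EUD|MUTE",
    "HG_TMO5": "EUD|TMO5",
    "HG_QUAC1": "EUD|QUAC1",
    "HG_STOMAGEN": "EUD|STOMAGEN",
}

_GENE_TREES = {
    "HG_MUTE": (
        "((HORN|mute_horn,MOS|mute_mos),(LYC|mute_lyc,(FERN|mute_fern,"
        "(CON|mute_con,(AMB|mute_amb,((MON1|mute_mon1,MON2|mute_mon2),"
        "EUD|MUTE))))));"
    ),
    "HG_TMO5": (
        "(MOS|tmo5_mos,(LYC|tmo5_lyc,(FERN|tmo5_fern,(CON|tmo5_con,"
        "(AMB|tmo5_amb,((MON1|tmo5_mon1,MON2|tmo5_mon2),EUD|TMO5))))));"
    ),
    "HG_STOMAGEN": (
        "(LYC|stom_lyc,(FERN|stom_fern,(CON|stom_con,(AMB|stom_amb,"
        "((MON1|stom_mon1,MON2|stom_mon2),EUD|STOMAGEN)))));"
    ),
    # one duplication in the seed-plant ancestor: two parallel seed clades
    "HG_QUAC1": (
        "(CHL|quac_chl,(CHA|quac_cha,((HORN|quac_horn,(LIV|quac_liv,"
        "MOS|quac_mos)),(FERN|quac_fern,((CON|quac_con1,(AMB|quac_amb1,"
        "((MON1|quac_mon1a,MON2|quac_mon2a),EUD|QUAC1))),"
        "(CON|quac_con2,(AMB|quac_amb2,((MON1|quac_mon1b,MON2|quac_mon2b),"
        "EUD|quac_eud2))))))));"
    ),
}

_TRAITS = (
    TraitAnnotation(
        name="stomatal_development",
        origin_node="Embryophyta",
        expansion_nodes=("Euphyllophyta", "Spermatophyta"),
        gene_ids=("EUD|MUTE", "EUD|QUAC1", "EUD|STOMAGEN"),
    ),
    TraitAnnotation(
        name="vascular_tissue",
        origin_node="Tracheophyta",
        expansion_nodes=("Spermatophyta",),
        gene_ids=("EUD|TMO5", "EUD|STOMAGEN"),
    ),
)


@dataclass
class WorkedExample:
    tree: SpeciesTree
    catalog: SpeciesCatalog
    hgs: list[HomologyGroup]
    occupancy: pd.DataFrame
    gene_trees: dict[str, str]
    traits: tuple[TraitAnnotation, ...]
    gene_to_hg: dict[str, str]


def _members_from_states(hg_id: str, states: dict[str, int]) -> HomologyGroup:
    """Build an HG whose members reproduce the intended occupancy row.

    Tree leaves are the authoritative member list where a gene tree exists;
    species with only transcriptome evidence get transcriptome-flagged
    members, matching what reciprocal-best-hit augmentation would produce.
    """
    if hg_id in _GENE_TREES:
        tree = load_gene_tree(_GENE_TREES[hg_id])
        members = {lf.taxon.label for lf in tree.leaf_nodes()}
    else:  # pragma: no cover - all fixture families carry trees
        members = {f"{sp}|{hg_id.lower()}_{sp.lower()}" for sp in states}
    member_species = {m: m.split("|", 1)[0] for m in members}
    evidence = {
        m: ("transcriptome" if sp in _TRANSCRIPTOME_TIPS else "genome")
        for m, sp in member_species.items()
    }
    return HomologyGroup(hg_id, members, member_species, evidence)


def worked_example() -> WorkedExample:
    """Assemble the packaged four-family fixture."""
    tree = backbone_tree()
    catalog = SpeciesCatalog(
        SpeciesInfo(
            code=tip,
            name=tip,
            source="transcriptome" if tip in _TRANSCRIPTOME_TIPS else "genome",
        )
        for tip in tree.tips
    )
    hgs = [_members_from_states(hg_id, states) for hg_id, states in _FAMILIES.items()]
    occupancy = build_occupancy(hgs, catalog)
    gene_to_hg = {
        gene: hg_id
        for hg_id, gene in _QUERY_GENES.items()
    }
    return WorkedExample(
        tree=tree,
        catalog=catalog,
        hgs=hgs,
        occupancy=occupancy,
        gene_trees=dict(_GENE_TREES),
        traits=_TRAITS,
        gene_to_hg=gene_to_hg,
    )


def classify_worked_example(
    example: WorkedExample | None = None,
) -> list[ModeCall]:
    """Run the full classification over the fixture, per trait gene list."""
    ex = example or worked_example()
    lookup = query_hgs_by_gene_ids(ex.hgs, sorted(ex.gene_to_hg))
    calls: list[ModeCall] = []
    for trait in ex.traits:
        for gene in trait.gene_ids:
            hg_id = lookup[gene]
            if hg_id is None:  # pragma: no cover - fixture genes all resolve
                continue
            row = ex.occupancy.loc[hg_id]
            origin = infer_origin_node(row, ex.tree, hg_id=hg_id)
            gtree = load_gene_tree(ex.gene_trees[hg_id])
            events = map_duplications(gtree, ex.tree)
            for ev in events:
                ev.hg_id = hg_id
            calls.append(
                classify_hg(origin, events, trait, row, ex.tree, ex.catalog)
            )
    return calls


def run_worked_example(outdir: str | Path) -> Path:
    """Classify the fixture and write its output tables (deterministic).

    Writes ``modes.tsv``, ``summary.tsv``, ``heatmap.tsv`` and
    ``calls.json``; byte-identical across runs.
    """
    ex = worked_example()
    calls = classify_worked_example(ex)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "hg_id": c.hg_id,
            "trait": c.trait,
            "origin_node": c.origin_label,
            "labels": "+".join(sorted(c.labels)) or "none",
            "expanded_at": ",".join(c.expanded_at),
            "retention_fraction": (
                "" if c.retention_fraction != c.retention_fraction
                else f"{c.retention_fraction:.4f}"
            ),
            "implied_losses": c.implied_losses,
        }
        for c in sorted(calls, key=lambda c: (c.trait, c.hg_id))
    ]
    pd.DataFrame(rows).to_csv(outdir / "modes.tsv", sep="\t", index=False)

    summary = summarize_modes(calls, list(ex.traits), ex.tree)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    gene_map = {g: ex.gene_to_hg[g] for g in sorted(ex.gene_to_hg)}
    heatmap = emit_heatmap_table(ex.occupancy, gene_map, ex.catalog, ex.tree)
    heatmap.to_csv(outdir / "heatmap.tsv", sep="\t")

    payload = {
        f"{c.trait}/{c.hg_id}": {
            "origin_node": c.origin_label,
            "labels": sorted(c.labels),
            "expanded_at": list(c.expanded_at),
            "implied_losses": c.implied_losses,
        }
        for c in calls
    }
    with open(outdir / "calls.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
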