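"""Classification of homology groups as novel, expanded or coopted.

For a trait anchored at a species-tree node (stomata at Embryophyta,
vascular tissue at Tracheophyta, ...) a homology group is

* **novel** — its inferred origin coincides with the trait's origin node
  (the genes and the innovation emerge together, absent from all
  outgroups);
* **coopted** — its origin strictly pre-dates the trait's origin *and* the
  group is retained across the trait clade (genome-evidence presence in at
  least ``retention_threshold`` of the clade's genome-sequenced species;
  default: all of them);
* **expanded** — at least one gene-tree duplication event maps to one of
  the trait's designated expansion nodes.

Novel and coopted are mutually exclusive; expanded combines freely with
either. A group whose origin is *younger* than the trait origin is
reported as ``post_origin`` for completeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .duplications import DuplicationEvent
from .occupancy import PRESENT, SpeciesCatalog
from .origins import OriginCall
from .species_tree import SpeciesTree

logger = logging.getLogger(__name__)

__all__ = [
    "TraitAnnotation",
    "ModeCall",
    "classify_hg",
    "summarize_modes",
    "emit_heatmap_table",
    "load_traits_yaml",
]


@dataclass(frozen=True)
class TraitAnnotation:
    """A trait, its origin node and the expansion nodes of interest."""

    name: str
    origin_node: str
    expansion_nodes: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"trait {self.name!r}: empty gene id list")


@dataclass
class ModeCall:
    """Per-HG, per-trait classification result."""

    hg_id: str
    trait: str
    origin_label: str
    labels: frozenset[str]
    expanded_at: tuple[str, ...] = ()
    retention_fraction: float = float("nan")
    implied_losses: int = 0

    def __post_init__(self):
        if {"novel", "coopted"} <= self.labels:
            raise ValueError(f"{self.hg_id}/{self.trait}: novel and coopted are exclusive")
        if ("expanded" in self.labels) != bool(self.expanded_at):
            raise ValueError(f"{self.hg_id}/{self.trait}: expanded_at inconsistent")


def load_traits_yaml(path: str) -> list[TraitAnnotation]:
    """Trait config: name -> {origin_node, expansion_nodes, gene_ids}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits = []
    for name, info in raw.items():
        traits.append(
            TraitAnnotation(
                name=name,
                origin_node=info["origin_node"],
                expansion_nodes=tuple(info.get("expansion_nodes", ())),
                gene_ids=tuple(info["gene_ids"]),
            )
        )
    return traits


def retention_fraction(
    row: Mapping[str, int],
    trait_node_label: str,
    tree: SpeciesTree,
    catalog: SpeciesCatalog,
) -> float:
    """Fraction of the trait clade's genome species with genome evidence.

    Transcriptome (partial) evidence does not count: retention asks whether
    every sequenced genome of the clade kept the gene.
    """
    clade = tree.node(trait_node_label).tip_set
    genome_in_clade = sorted(clade & catalog.genome_species())
    if not genome_in_clade:
        raise ValueError(
            f"trait clade {trait_node_label!r} contains no genome-sequenced species"
        )
    kept = sum(1 for sp in genome_in_clade if _get(row, sp) == PRESENT)
    return kept / len(genome_in_clade)


def _get(row: Mapping[str, int], key: str) -> int:
    try:
        return int(row[key])
    except (KeyError, IndexError):
        return 0


def classify_hg(
    origin: OriginCall,
    events: Sequence[DuplicationEvent],
    trait: TraitAnnotation,
    occupancy_row: Mapping[str, int],
    tree: SpeciesTree,
    catalog: SpeciesCatalog,
    retention_threshold: float = 1.0,
) -> ModeCall:
    """Classify one homology group against one trait annotation.

    See the module docstring for the label semantics. ``events`` should be
    the duplication events of this HG's gene tree (an empty list is fine:
    no expansion is called).
    """
    trait_node = tree.node(trait.origin_node)
    origin_node = origin.origin
    labels: set[str] = set()
    retention = float("nan")

    if origin_node is trait_node:
        labels.add("novel")
    elif tree.is_ancestor(origin_node, trait_node, strict=True):
        retention = retention_fraction(occupancy_row, trait.origin_node, tree, catalog)
        if retention >= retention_threshold:
            labels.add("coopted")
    elif tree.is_ancestor(trait_node, origin_node, strict=True):
        # origin younger than the innovation: narrated separately
        labels.add("post_origin")
    # origin in a disjoint subtree: no origin-relative label

    expanded_at = tuple(
        sorted({ev.mapped_label for ev in events if ev.mapped_label in trait.expansion_nodes})
    )
    if expanded_at:
        labels.add("expanded")

    return ModeCall(
        hg_id=origin.hg_id,
        trait=trait.name,
        origin_label=origin.origin_label,
        labels=frozenset(labels),
        expanded_at=expanded_at,
        retention_fraction=retention,
        implied_losses=origin.implied_losses,
    )


def summarize_modes(
    calls: Sequence[ModeCall],
    traits: Sequence[TraitAnnotation],
    tree: SpeciesTree,
) -> pd.DataFrame:
    """Per-trait counts of novel / coopted / expanded / post_origin HGs.

    ``predates_or_at_origin`` counts HGs whose origin node is the trait's
    origin or an ancestor of it. Traits without any call get a zero row
    (with a warning). Each label is counted independently, so a
    {coopted, expanded} call increments both columns.
    """
    if not calls and not traits:
        raise ValueError("nothing to summarize")
    rows = []
    by_trait: dict[str, list[ModeCall]] = {t.name: [] for t in traits}
    for call in calls:
        by_trait.setdefault(call.trait, []).append(call)
    for trait in traits:
        tcalls = by_trait[trait.name]
        if not tcalls:
            logger.warning("trait %s: no homology groups classified", trait.name)
        trait_node = tree.node(trait.origin_node)
        predate = 0
        for c in tcalls:
            if c.origin_label in tree:
                onode = tree.node(c.origin_label)
                if tree.is_ancestor(onode, trait_node, strict=False):
                    predate += 1
        rows.append(
            {
                "trait": trait.name,
                "n_hgs": len(tcalls),
                "novel": sum("novel" in c.labels for c in tcalls),
                "coopted": sum("coopted" in c.labels for c in tcalls),
                "expanded": sum("expanded" in c.labels for c in tcalls),
                "post_origin": sum("post_origin" in c.labels for c in tcalls),
                "predates_or_at_origin": predate,
            }
        )
    return pd.DataFrame(rows).sort_values("trait").reset_index(drop=True)


def emit_heatmap_table(
    occupancy: pd.DataFrame,
    gene_map: Mapping[str, str],
    catalog: SpeciesCatalog,
    tree: SpeciesTree,
) -> pd.DataFrame:
    """Gene-by-species state table in presentation order.

    Rows follow the input gene order; columns follow the species-tree tip
    order (restricted to catalog species). Genes sharing a homology group
    repeat that group's occupancy row and are flagged ``shared_hg``.
    """
    cols = [t for t in tree.tips if t in catalog and t in occupancy.columns]
    hg_counts: dict[str, int] = {}
    for hg in gene_map.values():
        hg_counts[hg] = hg_counts.get(hg, 0) + 1
    rows = []
    for gene, hg in gene_map.items():
        if hg not in occupancy.index:
            raise KeyError(f"gene {gene}: homology group {hg} has no occupancy row")
        rec = {"gene": gene, "hg_id": hg, "shared_hg": hg_counts[hg] > 1}
        for sp in cols:
            rec[sp] = int(occupancy.at[hg, sp])
        rows.append(rec)
    out = pd.DataFrame(rows, columns=["gene", "hg_id", "shared_hg", *cols])
    return out.set_index("gene")
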