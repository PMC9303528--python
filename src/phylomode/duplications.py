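"""Gene-tree rooting and duplication mapping by species overlap.

Gene trees (inferred elsewhere; consumed as Newick) are rooted against the
species phylogeny: the root goes on the branch separating the most
outgroup-ward species present in the tree. Duplication nodes are then
called by the species-overlap criterion — an internal node is a duplication
iff at least two of its child subtrees contain copies from overlapping
species sets — and each event is mapped to the species-tree LCA of the
node's descendant species. Counting the events mapped to a designated
ancestor (e.g. Spermatophyta) yields the per-node expansion calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy

from .blast import species_of
from .species_tree import Node, SpeciesTree

logger = logging.getLogger(__name__)

__all__ = [
    "DuplicationEvent",
    "load_gene_tree",
    "root_by_outgroup",
    "map_duplications",
    "expansions_at_nodes",
]


@dataclass
class DuplicationEvent:
    """One duplication: a gene-tree node mapped onto the species tree."""

    leafset: frozenset[str]  # gene-tree leaves under the duplication node
    mapped_node: Node
    mapped_label: str
    support: float | None = None
    low_support: bool = False
    hg_id: str | None = None


def load_gene_tree(source: str) -> dendropy.Tree:
    """Parse a gene tree from a Newick string or file path."""
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def _leaf_name(leaf) -> str:
    return leaf.taxon.label if leaf.taxon else leaf.label


def root_by_outgroup(
    tree: dendropy.Tree,
    species_rank: Sequence[str],
    delim: str = "|",
) -> dendropy.Tree:
    """Root a gene tree on the branch of its most outgroup-ward species.

    ``species_rank`` lists species codes from most-outgroup to most-ingroup
    (see :meth:`SpeciesTree.outgroup_rank`). The root is placed on the
    branch separating the leaf — or monophyletic leaf set — of the first
    listed species that occurs in the tree. Fallbacks: a non-monophyletic
    outgroup roots on its alphabetically first leaf; a tree with no listed
    outgroup species is midpoint-rooted (unit branch lengths are assumed
    where lengths are missing); trees with fewer than three leaves are
    returned unchanged. The input tree is not modified.
    """
    tree = tree.clone(depth=1)
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        logger.warning("gene tree with %d leaves: rooting skipped", len(leaves))
        return tree
    by_species: dict[str, list] = {}
    for leaf in leaves:
        by_species.setdefault(species_of(_leaf_name(leaf), delim), []).append(leaf)

    outgroup = next((sp for sp in species_rank if sp in by_species), None)
    if outgroup is None:
        logger.warning("no listed outgroup species in gene tree: midpoint rooting")
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.suppress_unifurcations()
        return tree

    og_leaves = sorted(by_species[outgroup], key=_leaf_name)
    if len(og_leaves) == 1:
        edge = og_leaves[0].edge
    else:
        # test unrooted monophyly from a vantage point outside the outgroup
        vantage = next(
            lf for lf in leaves
            if species_of(_leaf_name(lf), delim) != outgroup
        )
        tree.reroot_at_edge(vantage.edge, update_bipartitions=True)
        taxa = [lf.taxon for lf in tree.leaf_nodes()
                if species_of(_leaf_name(lf), delim) == outgroup]
        mrca = tree.mrca(taxa=taxa)
        if len(mrca.leaf_nodes()) == len(taxa):
            edge = mrca.edge
        else:
            logger.warning(
                "outgroup species %s not monophyletic: rooting on its first leaf",
                outgroup,
            )
            first = sorted(
                (lf for lf in tree.leaf_nodes()
                 if species_of(_leaf_name(lf), delim) == outgroup),
                key=_leaf_name,
            )[0]
            edge = first.edge
    tree.reroot_at_edge(edge, update_bipartitions=False)
    tree.suppress_unifurcations()
    return tree


def map_duplications(
    gtree: dendropy.Tree,
    stree: SpeciesTree,
    min_support: float = 0.0,
    delim: str = "|",
) -> list[DuplicationEvent]:
    """Call duplication events on a rooted gene tree.

    An internal node (>= 2 children) is a duplication iff at least two of
    its child subtrees contain overlapping species sets; the event maps to
    the species-tree LCA of the node's full descendant species set (a
    single species maps to its terminal branch). Multifurcations yield one
    conservative event. Events whose bootstrap support (read from internal
    node labels) is below ``min_support`` are flagged ``low_support`` but
    retained. A tree whose root is not strictly bifurcating is treated as
    unrooted and rejected.
    """
    seed = gtree.seed_node
    if len(seed.child_nodes()) != 2:
        raise ValueError(
            "gene tree root is not bifurcating: root it first (root_by_outgroup)"
        )
    events: list[DuplicationEvent] = []
    species_under: dict = {}
    leaves_under: dict = {}
    for node in gtree.postorder_node_iter():
        if node.is_leaf():
            name = _leaf_name(node)
            sp = species_of(name, delim)
            if sp not in stree:
                raise KeyError(f"gene-tree species {sp!r} not in species tree")
            species_under[node] = {sp}
            leaves_under[node] = frozenset([name])
            continue
        kids = node.child_nodes()
        species_under[node] = set().union(*(species_under[c] for c in kids))
        leaves_under[node] = frozenset().union(*(leaves_under[c] for c in kids))
        overlap = False
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                if species_under[kids[i]] & species_under[kids[j]]:
                    overlap = True
                    break
            if overlap:
                break
        if not overlap:
            continue
        mapped = stree.lca(species_under[node])
        support = _support_of(node)
        events.append(
            DuplicationEvent(
                leafset=leaves_under[node],
                mapped_node=mapped,
                mapped_label=mapped.label if mapped.label is not None else str(mapped.index),
                support=support,
                low_support=(support is not None and support < min_support),
            )
        )
    return events


def _support_of(node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def expansions_at_nodes(
    events: Sequence[DuplicationEvent],
    nodes: Sequence[str],
    stree: SpeciesTree,
) -> dict[str, int]:
    """Count duplication events mapped *exactly* to each listed node.

    Events mapped to descendants of a listed node do not count toward it.
    Unknown labels are fatal.
    """
    for label in nodes:
        if label not in stree:
            raise KeyError(f"unknown species-tree node label {label!r}")
    counts = {label: 0 for label in nodes}
    for ev in events:
        if ev.mapped_label in counts:
            counts[ev.mapped_label] += 1
    return counts
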