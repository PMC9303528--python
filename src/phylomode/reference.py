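"""Naive reference implementations used to validate the production code.

Everything here favours transparency over speed: dense matrices, exhaustive
enumeration, no pruning and no shared code with the optimized paths in
:mod:`phylomode.similarity`, :mod:`phylomode.origins` and
:mod:`phylomode.duplications`. Tests and the acceptance checks compare the
production implementations against these on small inputs.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np

from .blast import species_of
from .species_tree import Node, SpeciesTree

__all__ = [
    "dense_mcl_partition",
    "dollo_origin_bruteforce",
    "lca_mapping_duplications",
]


def dense_mcl_partition(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[set[int]]:
    """Dense, prune-free MCL run to convergence.

    Clusters are read as connected components of the support of the limit
    matrix, the textbook interpretation. Returns sets of matrix indices.
    """
    m = np.asarray(adjacency, dtype=float).copy()
    n = m.shape[0]
    if n == 0:
        return []
    m /= np.where(m.sum(axis=0) == 0, 1.0, m.sum(axis=0))
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m
        m = m ** inflation
        sums = m.sum(axis=0)
        sums[sums == 0] = 1.0
        m /= sums
        if np.max(np.abs(m - prev)) < tol:
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-7)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [set(c) for c in nx.connected_components(support)]


def _count_losses_under(gain: Node, present: set[str]) -> int:
    """Loss events = maximal all-absent subtrees hanging below ``gain``."""
    losses = 0
    stack = list(gain.children)
    while stack:
        node = stack.pop()
        if not (node.tip_set & present):
            losses += 1  # whole subtree lost in one event
        else:
            stack.extend(node.children)
    return losses


def dollo_origin_bruteforce(
    tree: SpeciesTree, presence_tips: Iterable[str]
) -> tuple[str | int, int]:
    """Exhaustive single-gain minimizer over every candidate gain node.

    Scans all nodes whose subtree covers the presence tips, counts the loss
    events each placement implies, and returns the placement with the fewest
    (ties to the most tipward candidate). Returns ``(node label or index,
    implied losses)``; unlabelled nodes are identified by preorder index.
    """
    present = set(presence_tips)
    if not present:
        raise ValueError("empty presence pattern")
    best: tuple[int, int] | None = None  # (losses, tip_set size)
    best_node: Node | None = None
    for node in tree.nodes:
        if not present <= node.tip_set:
            continue
        losses = _count_losses_under(node, present)
        key = (losses, len(node.tip_set))
        if best is None or key < best:
            best = key
            best_node = node
    assert best_node is not None
    return best_node.label if best_node.label is not None else best_node.index, best[0]


def lca_mapping_duplications(gene_tree, stree: SpeciesTree, delim: str = "|"):
    """Duplication nodes by the classic LCA-mapping reconciliation rule.

    Each gene-tree node maps to the species-tree LCA of its descendant
    species; a node is a duplication iff it maps to the same species-tree
    node as at least one of its children. ``gene_tree`` is a rooted dendropy
    tree with ``SPECIES|protein`` leaf names. Returns the set of duplication
    nodes as frozensets of descendant leaf names (a representation
    independent of any node-id convention).
    """
    mapping: dict = {}
    leaves: dict = {}
    events: set[frozenset[str]] = set()
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            leaves[node] = frozenset([name])
            mapping[node] = stree.node(species_of(name, delim))
        else:
            kids = node.child_nodes()
            leaves[node] = frozenset().union(*(leaves[c] for c in kids))
            species = set()
            for c in kids:
                species.update(species_of(n, delim) for n in leaves[c])
            mapping[node] = tree_lca(stree, species)
            if any(mapping[node] is mapping[c] for c in kids):
                events.add(leaves[node])
    return events


def tree_lca(stree: SpeciesTree, labels: Iterable[str]) -> Node:
    """LCA via explicit root-path intersection (independent of SpeciesTree.lca)."""
    paths = []
    for lab in labels:
        node = stree.node(lab)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))
    deepest = None
    for level in zip(*paths):
        if all(n is level[0] for n in level):
            deepest = level[0]
        else:
            break
    assert deepest is not None
    return deepest
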