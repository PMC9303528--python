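"""Protein similarity graph construction and Markov clustering (MCL).

The all-vs-all hit table is turned into an undirected weighted graph (edge
weight ``-log10(evalue)``, e-values floored at 1e-200, symmetrized by the
maximum over the two directions, self-loops set to each node's maximum
incident weight). Markov clustering then alternates expansion (matrix
squaring) and inflation (entrywise power followed by column renormalization)
of the column-stochastic transition matrix until the flow stabilizes;
clusters are read off as attractor systems. The inflation parameter (the
"granularity" of the clustering, default 2.0) controls how fine the
resulting homology groups are.

The iteration runs on ``scipy.sparse`` matrices with pruning of negligible
entries so large hit tables stay tractable; a naive dense reference used for
validation lives in :mod:`phylomode.reference`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log10
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .blast import HitRecord, species_of

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyGroup",
    "build_graph",
    "mcl_cluster",
    "mcl_partition",
    "hgs_from_partition",
]

#: e-values below this are clamped before the -log10 transform
EVALUE_FLOOR = 1e-200
#: minimum edge weight, keeps weights strictly positive for evalue ~ 1
MIN_WEIGHT = 1e-3
#: entries of the limit matrix above this count as attractor mass
ATTRACTOR_EPS = 1e-7


@dataclass
class HomologyGroup:
    """A cluster of proteins (orthologues plus paralogues).

    ``member_species`` maps each protein id to its species code;
    ``evidence`` records whether the member comes from a sequenced genome
    or was attached from transcriptome data by reciprocal best hit.
    """

    hg_id: str
    members: set[str]
    member_species: dict[str, str]
    evidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"{self.hg_id}: empty homology group")
        missing = self.members - self.member_species.keys()
        if missing:
            raise ValueError(f"{self.hg_id}: members without species: {sorted(missing)[:5]}")
        for m in self.members:
            self.evidence.setdefault(m, "genome")

    @property
    def species(self) -> set[str]:
        return set(self.member_species[m] for m in self.members)

    def members_by_species(self, code: str) -> list[str]:
        return sorted(m for m in self.members if self.member_species[m] == code)


def _edge_weight(evalue: float) -> float:
    return max(-log10(max(evalue, EVALUE_FLOOR)), MIN_WEIGHT)


def build_graph(hits: Iterable[HitRecord]) -> nx.Graph:
    """Build the undirected similarity graph MCL consumes.

    Edge weight for a pair is the maximum over the two hit directions of
    ``-log10(evalue)`` (floored at 1e-200). After all edges are placed every
    node receives a self-loop weighing as much as its strongest incident
    edge (1.0 for isolated nodes) — standard MCL preprocessing that stops
    weakly connected nodes from being absorbed artificially.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("no hits to build a graph from")
    graph = nx.Graph()
    for hit in hits:
        a, b = hit.query_id, hit.subject_id
        graph.add_node(a)
        graph.add_node(b)
        if a == b:
            continue  # self-loops are set during finalization
        w = _edge_weight(hit.evalue)
        if graph.has_edge(a, b):
            if w > graph[a][b]["weight"]:
                graph[a][b]["weight"] = w
        else:
            graph.add_edge(a, b, weight=w)
    # finalize: self-loop = max incident weight
    for node in graph.nodes:
        incident = [
            d["weight"] for _, nbr, d in graph.edges(node, data=True) if nbr != node
        ]
        graph.add_edge(node, node, weight=max(incident) if incident else 1.0)
    return graph


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    scale = sp.diags(1.0 / sums)
    return (m @ scale).tocsc()


def _prune(m: sp.csc_matrix, threshold: float) -> sp.csc_matrix:
    """Drop entries below ``threshold``, keeping each column's maximum."""
    if threshold <= 0:
        return m
    m = m.tocsc()
    keep = m.data >= threshold
    # never empty a column: retain the per-column max unconditionally
    for j in range(m.shape[1]):
        lo, hi = m.indptr[j], m.indptr[j + 1]
        if lo == hi:
            continue
        if not keep[lo:hi].any():
            keep[lo + int(np.argmax(m.data[lo:hi]))] = True
    m.data[~keep] = 0.0
    m.eliminate_zeros()
    return m


def mcl_partition(
    matrix: sp.spmatrix,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[list[set[int]], bool]:
    """Run MCL on a weighted adjacency matrix; return (clusters, converged).

    Clusters are sets of column indices. The iteration is the canonical
    expansion/inflation alternation on a column-stochastic matrix with
    pruning of entries below ``prune_threshold``; it stops when the largest
    entrywise change falls below ``tol`` or after ``max_iter`` rounds
    (non-convergence is logged and the final matrix is interpreted anyway).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = matrix.shape[0]
    if n == 0:
        return [], True
    m = _normalize_columns(sp.csc_matrix(matrix, dtype=float))
    converged = False
    for _ in range(max_iter):
        prev = m.copy()
        m = (m @ m).tocsc()  # expansion
        m.data **= inflation  # inflation
        m = _normalize_columns(m)
        m = _prune(m, prune_threshold)
        m = _normalize_columns(m)
        delta = abs(m - prev)
        if delta.nnz == 0 or delta.max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)
    return _read_clusters(m), converged


def _read_clusters(m: sp.csc_matrix) -> list[set[int]]:
    """Interpret the limit matrix: attractor systems and their basins.

    Attractors are nodes holding mass on their own diagonal. Attractors that
    share a column belong to one attractor system; every node joins the
    system of the attractors appearing in its column. A node whose column
    touches several systems (rare tie) goes to the system containing its
    smallest-index attractor; a node with no attractor in its column (only
    possible without convergence) follows its column's largest entry.
    """
    n = m.shape[0]
    m = m.tocsc()
    diag = m.diagonal()
    attractors = np.where(diag > ATTRACTOR_EPS)[0]
    is_attractor = np.zeros(n, dtype=bool)
    is_attractor[attractors] = True

    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    col_attr: list[list[int]] = []
    for j in range(n):
        rows = m.indices[m.indptr[j] : m.indptr[j + 1]]
        vals = m.data[m.indptr[j] : m.indptr[j + 1]]
        attrs = sorted(int(r) for r, v in zip(rows, vals) if is_attractor[r] and v > ATTRACTOR_EPS)
        col_attr.append(attrs)
        for other in attrs[1:]:
            union(attrs[0], other)

    clusters: dict[int, set[int]] = {}
    for j in range(n):
        attrs = col_attr[j]
        if attrs:
            root = find(attrs[0])  # attrs share one system after union
        else:
            lo, hi = m.indptr[j], m.indptr[j + 1]
            if lo == hi:
                root = j if j in parent else -j - 1  # fully isolated
            else:
                best = int(m.indices[lo + int(np.argmax(m.data[lo:hi]))])
                root = find(best) if best in parent else -best - 1
        clusters.setdefault(root, set()).add(j)
    return [clusters[k] for k in sorted(clusters)]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    species_delim: str = "|",
    evidence: Mapping[str, str] | None = None,
) -> list[HomologyGroup]:
    """Cluster a finalized similarity graph into homology groups.

    The graph must carry self-loops (see :func:`build_graph`). Returned
    groups partition the node set and are numbered by decreasing size (ties
    by smallest member id) as ``HG_0001``, ``HG_0002``, ...
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    for node in nodes:
        if not graph.has_edge(node, node):
            raise ValueError("graph not finalized: missing self-loops (use build_graph)")
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csc")
    index_clusters, _ = mcl_partition(
        adj, inflation=inflation, prune_threshold=prune_threshold,
        max_iter=max_iter, tol=tol,
    )
    partition = [{nodes[i] for i in cl} for cl in index_clusters]
    return hgs_from_partition(partition, species_delim=species_delim, evidence=evidence)


def hgs_from_partition(
    partition: Sequence[set[str]],
    species_delim: str = "|",
    evidence: Mapping[str, str] | None = None,
) -> list[HomologyGroup]:
    """Wrap a protein-id partition into :class:`HomologyGroup` objects."""
    ordered = sorted(partition, key=lambda c: (-len(c), min(c)))
    hgs = []
    for i, members in enumerate(ordered, start=1):
        hgs.append(
            HomologyGroup(
                hg_id=f"HG_{i:04d}",
                members=set(members),
                member_species={m: species_of(m, species_delim) for m in members},
                evidence={m: (evidence or {}).get(m, "genome") for m in members},
            )
        )
    return hgs
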