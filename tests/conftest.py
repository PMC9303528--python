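import networkx as nx
import numpy as np
import pytest

from phylomode import backbone_tree, worked_example


@pytest.fixture(scope="session")
def tree():
    return backbone_tree()


@pytest.fixture(scope="session")
def example():
    return worked_example()


def finalize(graph: nx.Graph) -> nx.Graph:
    """Add MCL self-loops (max incident weight) to a weighted graph."""
    for u in graph.nodes:
        inc = [d["weight"] for _, v, d in graph.edges(u, data=True) if v != u]
        graph.add_edge(u, u, weight=max(inc) if inc else 1.0)
    return graph


def random_weighted_graph(seed: int, max_nodes: int = 30) -> nx.Graph:
    """Random finalized weighted graph for MCL cross-checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, max_nodes + 1))
    g = nx.gnp_random_graph(n, 0.25, seed=seed)
    g = nx.relabel_nodes(g, lambda i: f"SP{i:02d}|p{i:02d}")
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(1, 100))
    return finalize(g)


def planted_block_graph(seed: int):
    """4 planted 5-node blocks (within-weight 50) plus <= 2 weight-1 noise edges.

    Returns (graph, truth mapping node -> block index).
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    truth = {}
    for b in range(4):
        nodes = [f"B{b}N{i}" for i in range(5)]
        for nd in nodes:
            truth[nd] = b
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(nodes[i], nodes[j], weight=50.0)
    for _ in range(int(rng.integers(0, 3))):
        a, b = rng.choice(20, size=2, replace=False)
        na, nb = f"B{a // 5}N{a % 5}", f"B{b // 5}N{b % 5}"
        if truth[na] != truth[nb] and not g.has_edge(na, nb):
            g.add_edge(na, nb, weight=1.0)
    return finalize(g), truth
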