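import itertools

import numpy as np
import pytest

from upm import ProbabilityGraph, example4_graph


@pytest.fixture
def ex4():
    return example4_graph()


@pytest.fixture
def triangle():
    """Triangle with all probabilities 1 (the exact-graph limit)."""
    return ProbabilityGraph(
        node_ids=["a", "b", "c"],
        edges={("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0},
    )


@pytest.fixture
def cycle4():
    return ProbabilityGraph(
        node_ids=["a", "b", "c", "d"],
        edges={("a", "b"): 0.5, ("b", "c"): 0.5, ("c", "d"): 0.5, ("a", "d"): 0.5},
    )


def random_connected_graph(rng, k, extra_edges=1, p_lo=0.2, p_hi=1.0):
    """Random connected probability graph: spanning tree + extra edges."""
    nodes = [f"u{i}" for i in range(k)]
    edges = {}
    for i in range(1, k):
        j = int(rng.integers(0, i))
        edges[tuple(sorted((nodes[j], nodes[i])))] = float(rng.uniform(p_lo, p_hi))
    pool = [
        tuple(sorted(e))
        for e in itertools.combinations(nodes, 2)
        if tuple(sorted(e)) not in edges
    ]
    n_extra = min(extra_edges, len(pool))
    if n_extra:
        for idx in rng.choice(len(pool), size=n_extra, replace=False):
            edges[pool[idx]] = float(rng.uniform(p_lo, p_hi))
    return ProbabilityGraph(node_ids=nodes, edges=edges)


def relabel_randomly(rng, g):
    """Random relabeling; returns (relabeled graph, mapping old->new)."""
    perm = rng.permutation(g.n_nodes)
    mapping = {g.node_ids[i]: g.node_ids[int(perm[i])] for i in range(g.n_nodes)}
    return g.relabeled(mapping), mapping


def jittered_copy(rng, g, jitter, floor=0.01):
    edges = {
        e: float(np.clip(p + rng.uniform(-jitter, jitter), floor, 1.0))
        for e, p in g.edges.items()
    }
    return ProbabilityGraph(node_ids=list(g.node_ids), edges=edges, directed=g.directed)
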