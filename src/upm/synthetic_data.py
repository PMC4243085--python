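"""Synthetic uncertain networks with planted patterns and ground truth.

Real probability networks (confidence-scored PPI or ChIP-derived
regulatory networks) are sparse, with edge probabilities spread over
(0, 1].  The generator emulates that setting: a uniform random simple
background graph with probabilities drawn from a configurable law, into
which a chosen k-node non-tree pattern can be planted several times on
disjoint node sets, each copy's edge probabilities independently
jittered by a bounded uniform perturbation.  The planted node sets are
returned as ground truth so cluster recovery can be scored exactly.

All randomness flows through one ``numpy.random.default_rng(seed)``
instance; a fixed seed reproduces the network bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graph_model import ProbabilityGraph

__all__ = ["GeneratorSpec", "example4_graph", "random_probability_network"]

#: lower clip for jittered probabilities, keeping them strictly positive
JITTER_FLOOR = 0.01


def example4_graph() -> ProbabilityGraph:
    """The 4-node, 5-edge reference probability graph used throughout.

    Edges: (v1,v2)=0.92, (v2,v3)=0.97, (v2,v4)=0.94, (v3,v4)=0.1,
    (v1,v4)=1.0 — a non-tree graph (one 4-cycle plus a chord) whose
    reduced conductance matrix with v4 grounded is
    [[1.92, -0.92, 0], [-0.92, 2.83, -0.97], [0, -0.97, 1.07]].
    """
    return ProbabilityGraph(
        node_ids=["v1", "v2", "v3", "v4"],
        edges={
            ("v1", "v2"): 0.92,
            ("v2", "v3"): 0.97,
            ("v2", "v4"): 0.94,
            ("v3", "v4"): 0.1,
            ("v1", "v4"): 1.0,
        },
    )


@dataclass
class GeneratorSpec:
    """Parameters of a synthetic uncertain network.

    ``probability_law`` is ``("uniform", lo, hi)`` with 0 < lo <= hi <= 1
    or ``("beta", a, b)`` truncated to (0, 1].  ``jitter`` is the maximum
    absolute per-edge perturbation applied to planted copies; jittered
    values are clipped to [JITTER_FLOOR, 1].
    """

    n_nodes: int
    n_edges: int
    probability_law: tuple = ("uniform", 0.3, 1.0)
    planted_pattern: ProbabilityGraph | None = None
    copies: int = 0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_edges > max_edges:
            raise ValueError(f"n_edges={self.n_edges} exceeds C(n,2)={max_edges}")
        if self.copies and self.planted_pattern is None:
            raise ValueError("copies > 0 requires a planted_pattern")
        if self.planted_pattern is not None:
            need = self.copies * self.planted_pattern.n_nodes
            if need > self.n_nodes:
                raise ValueError(
                    f"{self.copies} disjoint copies of a "
                    f"{self.planted_pattern.n_nodes}-node pattern need {need} nodes, "
                    f"host has {self.n_nodes}"
                )


def _draw_probabilities(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    name = law[0]
    if name == "uniform":
        lo, hi = law[1], law[2]
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"uniform bounds must satisfy 0 < lo <= hi <= 1, got {law}")
        return rng.uniform(lo, hi, size)
    if name == "beta":
        a, b = law[1], law[2]
        p = rng.beta(a, b, size)
        return np.clip(p, JITTER_FLOOR, 1.0)  # truncate away 0
    raise ValueError(f"unknown probability law {name!r}")


def random_probability_network(
    spec: GeneratorSpec,
) -> tuple[ProbabilityGraph, list[tuple[str, ...]]]:
    """Generate a network per `spec`; returns (graph, planted node sets).

    Background: `n_edges` edges sampled uniformly without replacement
    from all node pairs, probabilities from `probability_law`.  Each
    planted copy overwrites the induced topology on its (disjoint) node
    set with the pattern's edges, probabilities perturbed by independent
    uniform jitter in [-jitter, +jitter] and clipped to stay in (0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [f"n{i}" for i in range(spec.n_nodes)]
    pairs = list(itertools.combinations(range(spec.n_nodes), 2))
    chosen = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    probs = _draw_probabilities(rng, spec.probability_law, spec.n_edges)
    edges: dict[tuple[str, str], float] = {}
    for c, p in zip(chosen, probs):
        i, j = pairs[c]
        edges[(nodes[i], nodes[j])] = float(p)

    truth: list[tuple[str, ...]] = []
    if spec.planted_pattern is not None and spec.copies > 0:
        pat = spec.planted_pattern
        kp = pat.n_nodes
        slots = rng.choice(spec.n_nodes, size=spec.copies * kp, replace=False)
        for c in range(spec.copies):
            site = [nodes[s] for s in slots[c * kp : (c + 1) * kp]]
            site_set = set(site)
            # clear background edges inside the planted site
            edges = {
                e: p for e, p in edges.items()
                if not (e[0] in site_set and e[1] in site_set)
            }
            pat_idx = {n: i for i, n in enumerate(pat.node_ids)}
            for (u, v), p in sorted(pat.edges.items()):
                q = p + rng.uniform(-spec.jitter, spec.jitter)
                q = float(np.clip(q, JITTER_FLOOR, 1.0))
                a, b = site[pat_idx[u]], site[pat_idx[v]]
                key = (a, b) if a <= b else (b, a)
                edges[key] = q
            truth.append(tuple(site))

    g = ProbabilityGraph(node_ids=nodes, edges=edges, directed=False)
    return g, truth
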