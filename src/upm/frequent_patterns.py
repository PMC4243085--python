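"""Frequent probability-pattern discovery by two-step hierarchical clustering.

Candidate subgraphs are grouped into probability-isomorphism clusters;
a cluster's support is its member count and clusters with support >=
min_sup are the frequent patterns.

Step one avoids the O(n^2) distance matrix of classical agglomeration:
active clusters are paired at a stride of half the current cluster count
(cluster i with cluster i + ceil(Lc/2)), each pair that tests
probability-isomorphic is merged, and passes repeat until one completes
with no merge.  Step two is classical agglomeration on the few residual
clusters: the pair of representatives with the smallest voltage mismatch
(VMval) that still passes the isomorphism test is merged, until no pair
passes.

A cluster's representative is the support-weighted mean of its members'
probability adjacencies, aligned through the node mappings returned by
the isomorphism test, so it remains a valid probability graph summarizing
the cluster.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circuit_isomorphism import (
    IsoThresholds,
    default_threshold,
    iso_test,
    optimal_node_mapping,
    voltage_distance_matrix,
    voltage_matrix,
)
from .graph_model import ProbabilityGraph, SubgraphInstance, probability_adjacency
from .subgraph_enumeration import CandidateSet, collect_candidates

__all__ = [
    "Cluster",
    "MiningConfig",
    "PatternReport",
    "two_step_clustering",
    "merge_clusters",
    "frequent_clusters",
    "mine",
]


@dataclass
class Cluster:
    """A probability-isomorphism cluster of subgraph instances."""

    representative: ProbabilityGraph
    members: list[SubgraphInstance]
    _voltage_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def support(self) -> int:
        return len(self.members)

    def voltages(self, augment: bool) -> np.ndarray:
        if self._voltage_cache is None:
            self._voltage_cache = voltage_matrix(self.representative, augment=augment)
        return self._voltage_cache


@dataclass
class MiningConfig:
    """Parameters of a mining run.

    epsilon/theta default to ln(k(k-1)) when left as None; alpha (strict
    per-edge check) is off by default; `strict_merge` keeps the first
    member as representative instead of the weighted mean.
    """

    k: int
    epsilon: float | None = None
    theta: float | None = None
    alpha: float | None = None
    augment: bool = True
    min_sup: int = 1
    seed: int = 0
    directed: bool = False
    max_permutation_k: int = 8
    strict_merge: bool = False
    max_instances: int | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError(f"k must be >= 3, got {self.k}")
        if self.min_sup < 1:
            raise ValueError("min_sup must be >= 1")
        if self.epsilon is None:
            self.epsilon = default_threshold(self.k)
        if self.theta is None:
            self.theta = default_threshold(self.k)

    def thresholds(self) -> IsoThresholds:
        return IsoThresholds(
            epsilon=self.epsilon,
            theta=self.theta,
            alpha=self.alpha,
            augment=self.augment,
            max_permutation_k=self.max_permutation_k,
        )


def merge_clusters(a: Cluster, b: Cluster, mapping: Sequence[int]) -> Cluster:
    """Merge b into a under `mapping` (b's index matched to each a index).

    The new representative adjacency is the support-weighted mean
    (supA * A + supB * mapped(B)) / (supA + supB); members concatenate
    and support sums.  Probabilities stay in (0, 1] because a weighted
    mean of values in (0, 1] does — except where one graph has an edge
    the other lacks, in which case the mean over a 0 keeps the edge with
    a reduced probability.
    """
    da = probability_adjacency(a.representative)
    db = probability_adjacency(b.representative)
    perm = np.asarray(mapping, dtype=int)
    wa, wb = a.support, b.support
    merged = (wa * da + wb * db[np.ix_(perm, perm)]) / (wa + wb)
    nodes = list(a.representative.node_ids)
    edges = {
        (nodes[i], nodes[j]): float(merged[i, j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if merged[i, j] > 0
    }
    rep = ProbabilityGraph(node_ids=nodes, edges=edges, directed=a.representative.directed)
    return Cluster(representative=rep, members=a.members + b.members)


def _try_merge(a: Cluster, b: Cluster, cfg: MiningConfig) -> Cluster | None:
    """Merge b into a when the isomorphism test passes, else None."""
    thr = cfg.thresholds()
    verdict = iso_test(
        a.representative,
        b.representative,
        thr,
        sa=a.voltages(cfg.augment),
        sb=b.voltages(cfg.augment),
    )
    if not verdict.isomorphic:
        return None
    if cfg.strict_merge:
        merged = Cluster(representative=a.representative, members=a.members + b.members)
        merged._voltage_cache = a._voltage_cache
        return merged
    return merge_clusters(a, b, verdict.mapping)


def _stride_pass(clusters: list[Cluster], cfg: MiningConfig) -> tuple[list[Cluster], int]:
    """One stride-paired merging pass; returns (new clusters, merges)."""
    lc = len(clusters)
    half = lc // 2
    stride = math.ceil(lc / 2)
    out: list[Cluster] = []
    merges = 0
    for i in range(half):
        merged = _try_merge(clusters[i], clusters[i + stride], cfg)
        if merged is not None:
            out.append(merged)
            merges += 1
        else:
            out.append(clusters[i])
            out.append(clusters[i + stride])
    if lc % 2 == 1:  # odd middle element carried forward unchanged
        out.append(clusters[half])
    return out, merges


def _vmval(a: Cluster, b: Cluster, cfg: MiningConfig) -> float:
    dist = voltage_distance_matrix(a.voltages(cfg.augment), b.voltages(cfg.augment))
    return optimal_node_mapping(dist).vmval


def _agglomerate(clusters: list[Cluster], cfg: MiningConfig) -> list[Cluster]:
    """Classical smallest-VMval agglomeration on the residual clusters.

    A lazy heap of candidate pairs keyed by VMval avoids recomputing the
    full pairwise structure after each merge; stale entries (touching a
    consumed cluster version) are discarded on pop.  Pairs whose full
    isomorphism test fails stay failed for those cluster versions.
    """
    active: dict[int, Cluster] = dict(enumerate(clusters))
    next_id = len(clusters)
    heap: list[tuple[float, int, int]] = []
    for i, j in itertools.combinations(sorted(active), 2):
        heapq.heappush(heap, (_vmval(active[i], active[j], cfg), i, j))
    while heap:
        vm, i, j = heapq.heappop(heap)
        if i not in active or j not in active:
            continue
        if vm > cfg.epsilon:  # voltage filter: no pair below can pass either
            break
        merged = _try_merge(active[i], active[j], cfg)
        if merged is None:
            continue
        del active[i], active[j]
        mid = next_id
        next_id += 1
        for other in sorted(active):
            heapq.heappush(heap, (_vmval(merged, active[other], cfg), other, mid))
        active[mid] = merged
    return [active[i] for i in sorted(active)]


def two_step_clustering(candidates: CandidateSet, config: MiningConfig) -> list[Cluster]:
    """Cluster candidate subgraphs into probability-isomorphism groups.

    Phase 1 repeats stride-paired merging passes until a full pass makes
    no merge; phase 2 agglomerates the residual clusters by smallest
    representative VMval.  Deterministic given candidate order.
    """
    clusters = [
        Cluster(representative=inst.pattern, members=[inst])
        for inst in candidates.instances
    ]
    if not clusters:
        return []
    while len(clusters) > 1:
        clusters, merges = _stride_pass(clusters, config)
        if merges == 0:
            break
    return _agglomerate(clusters, config)


def frequent_clusters(clusters: list[Cluster], min_sup: int) -> list[Cluster]:
    """Clusters with support >= min_sup, by descending support.

    Ties keep first-seen order (stable sort).
    """
    if min_sup < 1:
        raise ValueError("min_sup must be >= 1")
    kept = [c for c in clusters if c.support >= min_sup]
    return sorted(kept, key=lambda c: -c.support)


@dataclass
class PatternReport:
    """Full outcome of a mining run, JSON-serializable via to_dict()."""

    config: MiningConfig
    n_candidates: int
    clusters: list[Cluster]

    def to_dict(self) -> dict:
        thr = self.config.thresholds()
        out = {
            "config": {
                "k": self.config.k,
                "epsilon": self.config.epsilon,
                "theta": self.config.theta,
                "alpha": self.config.alpha,
                "augment": self.config.augment,
                "min_sup": self.config.min_sup,
                "seed": self.config.seed,
                "directed": self.config.directed,
            },
            "n_candidates": self.n_candidates,
            "clusters": [],
        }
        for c in self.clusters:
            rep = c.representative
            pmvals = []
            for m in c.members:
                v = iso_test(rep, m.pattern, thr)
                pmvals.append(v.pmval if np.isfinite(v.pmval) else None)
            finite = [p for p in pmvals if p is not None]
            out["clusters"].append(
                {
                    "support": c.support,
                    "frequency": c.support / self.n_candidates if self.n_candidates else 0.0,
                    "representative": {
                        "nodes": list(rep.node_ids),
                        "edges": [[u, v, p] for (u, v), p in sorted(rep.edges.items())],
                    },
                    "members": [list(m.host_node_ids) for m in c.members],
                    "mean_pmval": float(np.mean(finite)) if finite else None,
                }
            )
        return out


def mine(host: ProbabilityGraph, config: MiningConfig) -> PatternReport:
    """Full pipeline: enumerate candidates, cluster, filter by support."""
    candidates = collect_candidates(host, config.k, max_instances=config.max_instances)
    clusters = two_step_clustering(candidates, config)
    frequent = frequent_clusters(clusters, config.min_sup)
    return PatternReport(
        config=config, n_candidates=len(candidates), clusters=frequent
    )
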