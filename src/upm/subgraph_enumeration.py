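"""Enumeration of connected k-node induced subgraphs, non-tree filter.

Candidate patterns for frequent-pattern mining are the connected induced
k-node subgraphs that contain at least one cycle (edge count >= k).
Tree-shaped subgraphs are excluded: the characterized biological motifs
of interest (feed-forward loops, bi-fans, ...) are non-tree, and trees
explode combinatorially without adding candidate patterns.

Enumeration is exact and uses the ESU (FANMOD-style) algorithm: each
connected k-subset is produced exactly once, in a deterministic order
given the host's node order.  Connectivity is always taken on the
underlying undirected graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .graph_model import ProbabilityGraph, SubgraphInstance, induced_subgraph

__all__ = [
    "CandidateSet",
    "EnumerationLimitError",
    "enumerate_connected_subgraphs",
    "is_nontree",
    "collect_candidates",
]


class EnumerationLimitError(RuntimeError):
    """Raised when enumeration exceeds a user-supplied instance cap."""


@dataclass
class CandidateSet:
    """All connected non-tree k-node induced subgraphs of a host network."""

    k: int
    instances: list[SubgraphInstance]

    def __len__(self) -> int:
        return len(self.instances)


def enumerate_connected_subgraphs(
    g: ProbabilityGraph, k: int
) -> Iterator[tuple[str, ...]]:
    """Yield every k-node subset inducing a connected subgraph, once each.

    ESU: for each root node v (in node order), grow extensions restricted
    to neighbors with index greater than v's, so each subset is found from
    exactly one root.  k > |V| yields nothing; k must be >= 2.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    order = {n: i for i, n in enumerate(g.node_ids)}
    adj = g.adjacency_lists()

    def extend(
        sub: list[str], extension: list[str], root_idx: int
    ) -> Iterator[tuple[str, ...]]:
        if len(sub) == k:
            yield tuple(sorted(sub, key=order.__getitem__))
            return
        ext = list(extension)
        while ext:
            w = ext.pop(0)
            # exclusive neighborhood: neighbors of w not adjacent to sub
            # and with index above the root
            sub_and_nbrs = set(sub)
            for s in sub:
                sub_and_nbrs |= adj[s]
            new_ext = ext + [
                u
                for u in sorted(adj[w], key=order.__getitem__)
                if order[u] > root_idx and u not in sub_and_nbrs
            ]
            yield from extend(sub + [w], new_ext, root_idx)

    for v in g.node_ids:
        ri = order[v]
        ext0 = [u for u in sorted(adj[v], key=order.__getitem__) if order[u] > ri]
        yield from extend([v], ext0, ri)


def is_nontree(instance: SubgraphInstance) -> bool:
    """True iff the (connected) pattern contains a cycle: edges >= nodes."""
    return instance.pattern.n_edges >= instance.pattern.n_nodes


def collect_candidates(
    g: ProbabilityGraph, k: int, max_instances: int | None = None
) -> CandidateSet:
    """Collect all connected non-tree k-node induced subgraphs.

    `max_instances` (None = unlimited) aborts with
    :class:`EnumerationLimitError` on combinatorial blow-up.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3 (smallest non-tree subgraph is a triangle), got {k}")
    instances: list[SubgraphInstance] = []
    for nodes in enumerate_connected_subgraphs(g, k):
        inst = SubgraphInstance(host_node_ids=nodes, pattern=induced_subgraph(g, nodes))
        if is_nontree(inst):
            instances.append(inst)
            if max_instances is not None and len(instances) > max_instances:
                raise EnumerationLimitError(
                    f"more than {max_instances} candidate subgraphs; "
                    "raise max_instances or reduce k"
                )
    return CandidateSet(k=k, instances=instances)
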