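"""Probability-graph data model and edge-list I/O.

An uncertain biological network (a PPI or regulatory network with
confidence-scored interactions) is modelled as a simple graph whose every
edge carries an existence probability in the half-open interval (0, 1].
A probability of exactly 0 is disallowed: such an edge is absent by
definition, and downstream circuit computations require strictly positive
conductances.

The canonical file format is a plain-text edge list, one edge per line::

    # comment lines start with '#'
    source  target  probability

separated by tabs or arbitrary whitespace.  An optional header line is
detected by a non-numeric third field and skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GraphValidationError",
    "ProbabilityGraph",
    "SubgraphInstance",
    "read_edge_list",
    "write_edge_list",
    "induced_subgraph",
    "probability_adjacency",
]


class GraphValidationError(ValueError):
    """Raised when input data violates the probability-graph invariants."""


def _canon(u: str, v: str) -> tuple[str, str]:
    """Canonical key for an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class ProbabilityGraph:
    """A simple graph with one probability per edge.

    Parameters
    ----------
    node_ids
        Node labels in a fixed order (first-appearance order when read
        from a file).  Labels are opaque strings.
    edges
        Mapping from a node pair to the edge probability.  For undirected
        graphs the key is stored in canonical (sorted) order; for directed
        graphs the key is the ordered (source, target) pair.
    directed
        Whether edge direction is significant.  Direction is carried by
        the data model but the circuit construction always symmetrizes.
    """

    node_ids: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    directed: bool = False

    def __post_init__(self) -> None:
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) < 1:
            raise GraphValidationError("graph must have at least one node")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise GraphValidationError("duplicate node labels")
        known = set(self.node_ids)
        normalized: dict[tuple[str, str], float] = {}
        for (u, v), p in self.edges.items():
            u, v = str(u), str(v)
            if u == v:
                raise GraphValidationError(f"self-loop on node {u!r}")
            if u not in known or v not in known:
                raise GraphValidationError(f"edge ({u!r}, {v!r}) references undeclared node")
            p = float(p)
            if not (0.0 < p <= 1.0):
                raise GraphValidationError(
                    f"edge ({u!r}, {v!r}) probability {p} outside (0, 1]"
                )
            key = (u, v) if self.directed else _canon(u, v)
            if key in normalized and normalized[key] != p:
                raise GraphValidationError(
                    f"duplicate edge ({u!r}, {v!r}) with conflicting probabilities"
                )
            normalized[key] = p
        self.edges = normalized

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def probability(self, u: str, v: str) -> float:
        """Probability of edge (u, v); 0.0 when the edge is absent."""
        key = (u, v) if self.directed else _canon(u, v)
        return self.edges.get(key, 0.0)

    def has_edge(self, u: str, v: str) -> bool:
        return self.probability(u, v) > 0.0

    def neighbors(self, u: str) -> list[str]:
        """Adjacent nodes (undirected sense), in node_ids order."""
        adj = set()
        for (a, b) in self.edges:
            if a == u:
                adj.add(b)
            elif b == u:
                adj.add(a)
        return [n for n in self.node_ids if n in adj]

    def adjacency_lists(self) -> dict[str, set[str]]:
        """Undirected adjacency sets for all nodes (one pass over edges)."""
        adj: dict[str, set[str]] = {n: set() for n in self.node_ids}
        for (a, b) in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def is_connected(self) -> bool:
        """Weak connectivity (direction ignored)."""
        if self.n_nodes == 0:
            return False
        adj = self.adjacency_lists()
        seen = {self.node_ids[0]}
        stack = [self.node_ids[0]]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_nodes

    def relabeled(self, mapping: Mapping[str, str]) -> "ProbabilityGraph":
        """Return a copy with every node label replaced via `mapping`."""
        return ProbabilityGraph(
            node_ids=[mapping[n] for n in self.node_ids],
            edges={(mapping[u], mapping[v]): p for (u, v), p in self.edges.items()},
            directed=self.directed,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbabilityGraph):
            return NotImplemented
        return (
            set(self.node_ids) == set(other.node_ids)
            and self.edges == other.edges
            and self.directed == other.directed
        )


@dataclass
class SubgraphInstance:
    """A k-node induced subgraph located in a host network.

    ``host_node_ids`` are the labels in the host; ``pattern`` is the
    induced probability graph on those nodes.
    """

    host_node_ids: tuple[str, ...]
    pattern: ProbabilityGraph

    def __post_init__(self) -> None:
        if set(self.host_node_ids) != set(self.pattern.node_ids):
            raise GraphValidationError("pattern nodes must equal host_node_ids")

    @property
    def k(self) -> int:
        return len(self.host_node_ids)


# -- I/O ---------------------------------------------------------------


def read_edge_list(path, directed: bool = False) -> ProbabilityGraph:
    """Read a whitespace-separated ``source target probability`` file.

    Lines starting with ``#`` are comments.  A single leading header line
    is tolerated when its third field is not numeric.  Node order is
    first-appearance order.
    """
    node_ids: list[str] = []
    seen: set[str] = set()
    edges: dict[tuple[str, str], float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise GraphValidationError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            u, v, ptxt = fields
            try:
                p = float(ptxt)
            except ValueError:
                if not edges and not node_ids:
                    continue  # header line
                raise GraphValidationError(
                    f"{path}:{lineno}: probability {ptxt!r} is not a number"
                ) from None
            if u == v:
                raise GraphValidationError(f"{path}:{lineno}: self-loop on {u!r}")
            if not (0.0 < p <= 1.0):
                raise GraphValidationError(
                    f"{path}:{lineno}: probability {p} outside (0, 1]"
                )
            key = (u, v) if directed else _canon(u, v)
            if key in edges and edges[key] != p:
                raise GraphValidationError(
                    f"{path}:{lineno}: duplicate edge ({u}, {v}) with conflicting probability"
                )
            for n in (u, v):
                if n not in seen:
                    seen.add(n)
                    node_ids.append(n)
            edges[key] = p
    if not node_ids:
        raise GraphValidationError(f"{path}: no edges found")
    return ProbabilityGraph(node_ids=node_ids, edges=edges, directed=directed)


def write_edge_list(g: ProbabilityGraph, path) -> None:
    """Write the same dialect `read_edge_list` accepts, full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# source\ttarget\tprobability\n")
        for (u, v), p in sorted(g.edges.items()):
            fh.write(f"{u}\t{v}\t{p!r}\n")


# -- derived structures ------------------------------------------------


def induced_subgraph(g: ProbabilityGraph, nodes: Iterable[str]) -> ProbabilityGraph:
    """Induced subgraph on `nodes`, host probabilities preserved.

    Node order follows the host's node order.
    """
    nodeset = {str(n) for n in nodes}
    unknown = nodeset - set(g.node_ids)
    if unknown:
        raise GraphValidationError(f"unknown node labels: {sorted(unknown)}")
    sub_nodes = [n for n in g.node_ids if n in nodeset]
    sub_edges = {
        (u, v): p for (u, v), p in g.edges.items() if u in nodeset and v in nodeset
    }
    return ProbabilityGraph(node_ids=sub_nodes, edges=sub_edges, directed=g.directed)


def probability_adjacency(
    g: ProbabilityGraph, node_order: Sequence[str] | None = None
) -> np.ndarray:
    """Probability adjacency matrix in the given node order.

    Entry (i, j) is the probability of edge (node_order[i], node_order[j])
    or 0 for absent edges; the diagonal is zero and the matrix is
    symmetric for undirected graphs.
    """
    order = list(g.node_ids) if node_order is None else [str(n) for n in node_order]
    if sorted(order) != sorted(g.node_ids):
        raise GraphValidationError("node_order must be a permutation of the graph's nodes")
    idx = {n: i for i, n in enumerate(order)}
    k = len(order)
    d = np.zeros((k, k))
    for (u, v), p in g.edges.items():
        d[idx[u], idx[v]] = p
        if not g.directed:
            d[idx[v], idx[u]] = p
    return d
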