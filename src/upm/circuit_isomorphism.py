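"""Probability-graph isomorphism via associated-circuit node voltages.

Two k-node probability graphs are *probability isomorphic* when some node
bijection makes every corresponding edge-probability difference small
(|delta_ij| <= alpha, optional) and the total absolute difference small
(sum |delta_ij| <= theta).  Testing all k! bijections directly is
expensive, so a circuit-based necessary-condition filter is applied
first:

1.  Replace every edge of probability p by a resistor of conductance p
    (resistance 1/p) — the *associated circuit*.  An edge with p near 0
    is nearly an open circuit, matching its near-absence from the graph.
2.  For each choice of reference node i, inject a unit current source
    (1 A) into every other node, returned through the reference
    (*complete excitation*), and solve the node-voltage equations
    G U = I with the reduced (k-1)x(k-1) conductance matrix G.  The
    ascending-sorted voltages form the *node voltage sequence* S_i; the
    k sequences stacked form the voltage matrix S.  S is a node
    invariant: relabeling the graph only permutes its rows.
3.  Build the squared-Euclidean distance matrix between the rows of S
    and S', and solve the assignment problem (Hungarian algorithm).  The
    optimal cost is VMval, the minimum voltage-sequence mismatch over
    all node bijections.  Probability-isomorphic graphs have similar
    circuits, hence similar voltages: VMval > epsilon rejects the pair
    outright.
4.  Under the optimal assignment, compare probability adjacencies:
    PMval = sum over ordered index pairs of |p - p'|.  PMval <= theta
    accepts; otherwise remaining bijections are searched (with
    branch-and-bound pruning) before rejecting.

Optionally each row of S is augmented with its mean and (population)
variance before the distance computation, sharpening the VMval filter
at no extra solve cost.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve as _dense_solve
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .graph_model import ProbabilityGraph, probability_adjacency

__all__ = [
    "CircuitSystem",
    "AssignmentResult",
    "IsoThresholds",
    "IsoVerdict",
    "DisconnectedGraphError",
    "PermutationCapError",
    "default_threshold",
    "reduced_conductance_matrix",
    "node_voltage_sequence",
    "voltage_matrix",
    "voltage_distance_matrix",
    "optimal_node_mapping",
    "adjacency_mismatch",
    "iso_test",
    "brute_force_iso",
]

#: absolute tolerance for voltage / mismatch comparisons
VOLTAGE_ATOL = 1e-9


class DisconnectedGraphError(ValueError):
    """The associated circuit is undefined for a disconnected graph."""


class PermutationCapError(RuntimeError):
    """The exhaustive mapping search was refused for too large k."""


def default_threshold(k: int) -> float:
    """Default mismatch threshold ln(k(k-1)) for k-node subgraphs.

    Empirically the upper limit at which clusters remain coherent while
    their number stays small; used for both epsilon and theta.
    """
    return math.log(k * (k - 1))


# -- associated circuit ------------------------------------------------


@dataclass
class CircuitSystem:
    """Reduced node-voltage system of the associated circuit.

    ``conductance_matrix`` is the (k-1)x(k-1) reduced Laplacian over the
    non-reference nodes (self-admittance on the diagonal, negated edge
    probability off it); ``excitation_vector`` is the net injected
    current at each non-reference node (all +1 A under complete
    excitation of the reference node).
    """

    reference: int
    non_reference: list[int]
    conductance_matrix: np.ndarray
    excitation_vector: np.ndarray


def reduced_conductance_matrix(g: ProbabilityGraph, reference: int) -> CircuitSystem:
    """Build the reduced conductance system with node `reference` grounded.

    Conductances equal edge probabilities (R = 1/p).  Directed graphs are
    symmetrized: the circuit has no notion of direction.
    """
    if not g.is_connected():
        raise DisconnectedGraphError("circuit undefined for disconnected graph")
    k = g.n_nodes
    if not (0 <= reference < k):
        raise IndexError(f"reference index {reference} out of range for k={k}")
    others = [i for i in range(k) if i != reference]
    pos = {node_idx: row for row, node_idx in enumerate(others)}
    G = np.zeros((k - 1, k - 1))
    labels = g.node_ids
    idx = {n: i for i, n in enumerate(labels)}
    for (u, v), p in g.edges.items():
        iu, iv = idx[u], idx[v]
        if iu != reference:
            G[pos[iu], pos[iu]] += p
        if iv != reference:
            G[pos[iv], pos[iv]] += p
        if iu != reference and iv != reference:
            G[pos[iu], pos[iv]] -= p
            G[pos[iv], pos[iu]] -= p
    return CircuitSystem(
        reference=reference,
        non_reference=others,
        conductance_matrix=G,
        excitation_vector=np.ones(k - 1),
    )


def node_voltage_sequence(g: ProbabilityGraph, reference: int) -> np.ndarray:
    """Ascending node voltages under complete excitation of `reference`.

    Solves G U = 1 for the reduced system; all voltages are strictly
    positive for a connected graph with positive probabilities.
    """
    sys = reduced_conductance_matrix(g, reference)
    try:
        u = _dense_solve(sys.conductance_matrix, sys.excitation_vector, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - connected => SPD
        raise np.linalg.LinAlgError(
            f"singular node-voltage system for graph with nodes {g.node_ids} "
            f"(reference index {reference}): {exc}"
        ) from exc
    return np.sort(u)


def voltage_matrix(g: ProbabilityGraph, augment: bool = True) -> np.ndarray:
    """Stack the node voltage sequences of all k reference choices.

    Row i is the ascending sequence with node i as reference (length
    k-1).  With ``augment`` each row gains its mean and population
    variance as two trailing entries, so rows have length k+1.
    """
    k = g.n_nodes
    if k < 2:
        raise ValueError("voltage matrix requires at least 2 nodes")
    rows = np.vstack([node_voltage_sequence(g, i) for i in range(k)])
    if augment:
        mean = rows.mean(axis=1, keepdims=True)
        var = rows.var(axis=1, keepdims=True)  # population variance
        rows = np.hstack([rows, mean, var])
    return rows


# -- voltage-sequence alignment ----------------------------------------


def voltage_distance_matrix(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of two voltage matrices."""
    sa = np.asarray(sa, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if sa.ndim != 2 or sb.ndim != 2 or sa.shape[1] != sb.shape[1]:
        raise ValueError(f"row-length mismatch: {sa.shape} vs {sb.shape}")
    return cdist(sa, sb, metric="sqeuclidean")


@dataclass
class AssignmentResult:
    """Minimum-cost node alignment between two voltage matrices."""

    mapping: tuple[int, ...]  # mapping[i] = column assigned to row i
    assignment_matrix: np.ndarray
    vmval: float


def optimal_node_mapping(dist: np.ndarray) -> AssignmentResult:
    """Solve the assignment problem on a distance matrix (Hungarian).

    Returns the bijection minimizing the sum of assigned entries; the
    achieved sum is VMval.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dist.shape}")
    rows, cols = linear_sum_assignment(dist)
    mapping = tuple(int(c) for c in cols[np.argsort(rows)])
    m = np.zeros_like(dist, dtype=int)
    m[rows, cols] = 1
    return AssignmentResult(
        mapping=mapping,
        assignment_matrix=m,
        vmval=float(dist[rows, cols].sum()),
    )


def adjacency_mismatch(
    ga: ProbabilityGraph, gb: ProbabilityGraph, mapping: Sequence[int]
) -> float:
    """PMval: total |p - p'| over all ordered index pairs under `mapping`.

    ``mapping[i]`` is the gb node index matched to ga node index i.
    Absent edges contribute probability 0.  The sum runs over ordered
    pairs, so for undirected graphs each edge difference is counted
    twice.
    """
    da = probability_adjacency(ga)
    db = probability_adjacency(gb)
    perm = np.asarray(mapping, dtype=int)
    if sorted(perm.tolist()) != list(range(len(db))):
        raise ValueError("mapping must be a bijection of node indices")
    return float(np.abs(da - db[np.ix_(perm, perm)]).sum())


# -- isomorphism decision ----------------------------------------------


@dataclass
class IsoThresholds:
    """Thresholds controlling the probability-isomorphism decision.

    ``epsilon`` bounds VMval (voltage filter), ``theta`` bounds PMval
    (adjacency criterion).  ``alpha`` optionally re-enables the strict
    per-edge |delta| <= alpha check inside the accepting stages; it is
    off by default because the voltage filter already plays its role at
    a fraction of the cost.  ``max_permutation_k`` caps the k!-fallback.
    """

    epsilon: float
    theta: float
    alpha: float | None = None
    augment: bool = True
    max_permutation_k: int = 8

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.theta < 0:
            raise ValueError("epsilon and theta must be >= 0")
        if self.alpha is not None and not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class IsoVerdict:
    """Outcome of the staged isomorphism test."""

    isomorphic: bool
    vmval: float
    pmval: float
    mapping: tuple[int, ...] | None
    stage: str  # size-mismatch | voltage-filter | hungarian-accept |
    #            permutation-accept | permutation-reject


def _passes(
    da: np.ndarray, db: np.ndarray, perm: np.ndarray, theta: float, alpha: float | None
) -> tuple[bool, float]:
    """Check one bijection against theta (and alpha when set)."""
    diff = np.abs(da - db[np.ix_(perm, perm)])
    pmval = float(diff.sum())
    ok = pmval <= theta + VOLTAGE_ATOL
    if ok and alpha is not None:
        ok = float(diff.max()) <= alpha + VOLTAGE_ATOL
    return ok, pmval


def _permutation_search(
    da: np.ndarray,
    db: np.ndarray,
    skip: tuple[int, ...],
    theta: float,
    alpha: float | None,
) -> tuple[int, ...] | None:
    """Branch-and-bound search over bijections for PMval <= theta.

    Builds the mapping index by index in lexicographic order, pruning
    when the partial mismatch (over fully-assigned pairs) already
    exceeds theta; returns the first satisfying bijection, or None.
    """
    k = da.shape[0]

    def rec(prefix: list[int], used: set[int], partial: float):
        i = len(prefix)
        if i == k:
            perm = tuple(prefix)
            if perm == skip:
                return None
            ok, _ = _passes(da, db, np.array(perm), theta, alpha)
            return perm if ok else None
        for c in range(k):
            if c in used:
                continue
            add = 0.0
            bad = False
            for j in range(i):
                d = abs(da[i, j] - db[c, prefix[j]]) + abs(da[j, i] - db[prefix[j], c])
                if alpha is not None and d / 2 > alpha + VOLTAGE_ATOL:
                    bad = True
                    break
                add += d
            if bad or partial + add > theta + VOLTAGE_ATOL:
                continue
            hit = rec(prefix + [c], used | {c}, partial + add)
            if hit is not None:
                return hit
        return None

    return rec([], set(), 0.0)


def iso_test(
    ga: ProbabilityGraph,
    gb: ProbabilityGraph,
    thresholds: IsoThresholds,
    sa: np.ndarray | None = None,
    sb: np.ndarray | None = None,
) -> IsoVerdict:
    """Staged probability-isomorphism decision.

    Stage 1 computes voltage matrices (pass `sa` / `sb` to reuse cached
    ones), aligns them by the Hungarian algorithm and rejects when
    VMval > epsilon.  Stage 2 accepts when PMval under the optimal
    alignment is <= theta.  Stage 3 searches the remaining bijections
    (branch-and-bound) for any with PMval <= theta.
    """
    if ga.n_nodes != gb.n_nodes:
        return IsoVerdict(False, math.inf, math.inf, None, "size-mismatch")
    if sa is None:
        sa = voltage_matrix(ga, augment=thresholds.augment)
    if sb is None:
        sb = voltage_matrix(gb, augment=thresholds.augment)
    assign = optimal_node_mapping(voltage_distance_matrix(sa, sb))
    if assign.vmval > thresholds.epsilon + VOLTAGE_ATOL:
        return IsoVerdict(False, assign.vmval, math.inf, assign.mapping, "voltage-filter")

    da = probability_adjacency(ga)
    db = probability_adjacency(gb)
    ok, pmval = _passes(
        da, db, np.array(assign.mapping), thresholds.theta, thresholds.alpha
    )
    if ok:
        return IsoVerdict(True, assign.vmval, pmval, assign.mapping, "hungarian-accept")

    k = ga.n_nodes
    if k > thresholds.max_permutation_k:
        raise PermutationCapError(
            f"exhaustive mapping search needed for k={k} exceeds "
            f"max_permutation_k={thresholds.max_permutation_k}; raise the cap"
        )
    hit = _permutation_search(
        da, db, assign.mapping, thresholds.theta, thresholds.alpha
    )
    if hit is not None:
        _, pm = _passes(da, db, np.array(hit), thresholds.theta, thresholds.alpha)
        return IsoVerdict(True, assign.vmval, pm, hit, "permutation-accept")
    return IsoVerdict(False, assign.vmval, pmval, assign.mapping, "permutation-reject")


def brute_force_iso(
    ga: ProbabilityGraph,
    gb: ProbabilityGraph,
    alpha: float = 1.0,
    theta: float = 0.0,
) -> tuple[bool, tuple[int, ...], float]:
    """Exhaustive reference decision over all k! bijections.

    Returns (isomorphic, best_mapping, best_pmval) where best_mapping
    minimizes the ordered-pair mismatch sum and `isomorphic` is true iff
    some bijection satisfies both max |delta| <= alpha and
    sum |delta| <= theta.  Intended as an oracle for small k.
    """
    if ga.n_nodes != gb.n_nodes:
        return False, (), math.inf
    k = ga.n_nodes
    if k > 8:
        raise PermutationCapError(f"brute force refused for k={k} > 8")
    da = probability_adjacency(ga)
    db = probability_adjacency(gb)
    best_perm: tuple[int, ...] = tuple(range(k))
    best_pm = math.inf
    found = False
    for perm in itertools.permutations(range(k)):
        p = np.array(perm)
        diff = np.abs(da - db[np.ix_(p, p)])
        pm = float(diff.sum())
        if pm < best_pm:
            best_pm, best_perm = pm, perm
        if (
            pm <= theta + VOLTAGE_ATOL
            and float(diff.max()) <= alpha + VOLTAGE_ATOL
        ):
            found = True
    return found, best_perm, best_pm
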