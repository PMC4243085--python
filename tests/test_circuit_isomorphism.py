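"""Tests for the associated-circuit isomorphism machinery.

The 4-node reference graph's printed voltage values (6 decimals) anchor
the circuit construction; assignment, mismatch and the staged decision
are checked against exhaustive-permutation oracles computed inline.
"""

import itertools
import math

import numpy as np
import pytest

from upm import (
    DisconnectedGraphError,
    IsoThresholds,
    PermutationCapError,
    ProbabilityGraph,
    adjacency_mismatch,
    brute_force_iso,
    default_threshold,
    iso_test,
    node_voltage_sequence,
    optimal_node_mapping,
    probability_adjacency,
    reduced_conductance_matrix,
    voltage_distance_matrix,
    voltage_matrix,
)

from conftest import jittered_copy, random_connected_graph, relabel_randomly

# printed six-decimal voltage sequences of the reference graph, rows v1..v4
PRINTED_S = np.array(
    [
        [1.413642, 1.724302, 2.629848],
        [1.034504, 1.069194, 1.077705],
        [2.726954, 3.548548, 3.675701],
        [1.277978, 1.580127, 2.367031],
    ]
)


class TestConductanceMatrix:
    def test_reference_graph_grounded_at_v4(self, ex4):
        sys = reduced_conductance_matrix(ex4, 3)
        expected = np.array(
            [[1.92, -0.92, 0.0], [-0.92, 2.83, -0.97], [0.0, -0.97, 1.07]]
        )
        np.testing.assert_allclose(sys.conductance_matrix, expected, atol=1e-12)
        np.testing.assert_allclose(sys.excitation_vector, np.ones(3))

    def test_unit_triangle(self, triangle):
        sys = reduced_conductance_matrix(triangle, 0)
        np.testing.assert_allclose(sys.conductance_matrix, [[2, -1], [-1, 2]])

    def test_single_edge(self):
        g = ProbabilityGraph(node_ids=["a", "b"], edges={("a", "b"): 0.5})
        sys = reduced_conductance_matrix(g, 0)
        np.testing.assert_allclose(sys.conductance_matrix, [[0.5]])

    def test_disconnected_graph_rejected(self):
        g = ProbabilityGraph(
            node_ids=["a", "b", "c", "d"], edges={("a", "b"): 0.5, ("c", "d"): 0.5}
        )
        with pytest.raises(DisconnectedGraphError):
            reduced_conductance_matrix(g, 0)

    def test_row_sums_equal_conductance_to_reference(self, ex4):
        sys = reduced_conductance_matrix(ex4, 3)
        for row, node_idx in enumerate(sys.non_reference):
            expected = ex4.probability(ex4.node_ids[node_idx], ex4.node_ids[3])
            assert sys.conductance_matrix[row].sum() == pytest.approx(expected)


class TestVoltageSequences:
    @pytest.mark.parametrize("ref", range(4))
    def test_printed_values_reproduced(self, ex4, ref):
        np.testing.assert_allclose(
            node_voltage_sequence(ex4, ref), PRINTED_S[ref], atol=5e-7
        )

    def test_unit_triangle_voltages(self, triangle):
        np.testing.assert_allclose(node_voltage_sequence(triangle, 0), [1.0, 1.0])

    def test_voltage_matrix_rows(self, ex4):
        np.testing.assert_allclose(voltage_matrix(ex4, augment=False), PRINTED_S, atol=5e-7)

    def test_augmentation_appends_mean_and_population_variance(self, triangle):
        vm = voltage_matrix(triangle, augment=True)
        assert vm.shape == (3, 4)
        np.testing.assert_allclose(vm, [[1.0, 1.0, 1.0, 0.0]] * 3, atol=1e-12)

    def test_rows_ascending_and_positive(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_connected_graph(rng, int(rng.integers(3, 7)), extra_edges=2)
            vm = voltage_matrix(g, augment=False)
            assert (vm > 0).all()
            assert (np.diff(vm, axis=1) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_relabeling_permutes_rows_only(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, 5, extra_edges=3)
        h, _ = relabel_randomly(rng, g)
        a = np.sort(voltage_matrix(g, augment=False), axis=0)
        b = np.sort(voltage_matrix(h, augment=False), axis=0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_scaling_law_halving_probabilities_doubles_voltages(self, ex4):
        scaled = ProbabilityGraph(
            node_ids=list(ex4.node_ids),
            edges={e: 0.5 * p for e, p in ex4.edges.items()},
        )
        v1 = voltage_matrix(ex4, augment=False)
        v2 = voltage_matrix(scaled, augment=False)
        np.testing.assert_allclose(v2, 2.0 * v1, rtol=1e-12)


class TestDistanceAndAssignment:
    def test_self_distance_zero_diagonal(self, ex4):
        d = voltage_distance_matrix(*(voltage_matrix(ex4),) * 2)
        np.testing.assert_allclose(np.diag(d), 0, atol=1e-12)

    def test_squared_euclidean_value(self):
        d = voltage_distance_matrix(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))
        assert d[0, 0] == pytest.approx(2.0)

    def test_printed_rows_distance(self, ex4):
        vm = voltage_matrix(ex4, augment=False)
        d = voltage_distance_matrix(vm, vm)
        brute = float(((PRINTED_S[0] - PRINTED_S[2]) ** 2).sum())
        assert d[0, 2] == pytest.approx(brute, abs=1e-5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            voltage_distance_matrix(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_trivial_assignments(self):
        assert optimal_node_mapping(np.array([[0.0, 2.0], [2.0, 0.0]])).mapping == (0, 1)
        res = optimal_node_mapping(np.array([[5.0, 1.0], [1.0, 5.0]]))
        assert res.mapping == (1, 0) and res.vmval == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_hungarian_matches_permutation_minimum(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.uniform(0, 10, size=(5, 5))
        best = min(
            sum(cost[i, p[i]] for i in range(5))
            for p in itertools.permutations(range(5))
        )
        assert optimal_node_mapping(cost).vmval == pytest.approx(best)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            optimal_node_mapping(np.zeros((2, 3)))


class TestAdjacencyMismatch:
    def test_identity_is_zero(self, ex4):
        assert adjacency_mismatch(ex4, ex4, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_single_edge_change_counted_twice(self, ex4):
        mod = ProbabilityGraph(
            node_ids=list(ex4.node_ids),
            edges={**ex4.edges, ("v3", "v4"): 0.2},
        )
        assert adjacency_mismatch(ex4, mod, (0, 1, 2, 3)) == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ga = random_connected_graph(rng, 4, extra_edges=2)
        gb = random_connected_graph(rng, 4, extra_edges=1)
        perm = tuple(int(i) for i in rng.permutation(4))
        P = np.eye(4)[list(perm)]
        da, db = probability_adjacency(ga), probability_adjacency(gb)
        oracle = float(np.abs(da - P @ db @ P.T).sum())
        assert adjacency_mismatch(ga, gb, perm) == pytest.approx(oracle)

    def test_non_bijection_rejected(self, ex4):
        with pytest.raises(ValueError):
            adjacency_mismatch(ex4, ex4, (0, 0, 1, 2))


def min_pmval_oracle(ga, gb):
    """Exhaustive minimum ordered-pair mismatch over all bijections."""
    da, db = probability_adjacency(ga), probability_adjacency(gb)
    k = ga.n_nodes
    return min(
        float(np.abs(da - db[np.ix_(p, p)]).sum())
        for p in map(list, itertools.permutations(range(k)))
    )


class TestIsoTest:
    def test_self_isomorphism_at_zero_thresholds(self, ex4):
        v = iso_test(ex4, ex4, IsoThresholds(epsilon=0.0, theta=0.0))
        assert v.isomorphic and v.vmval <= 1e-9 and v.pmval <= 1e-9

    def test_perturbed_relabeled_copy_accepted_at_default_thresholds(self, ex4):
        rng = np.random.default_rng(3)
        other, _ = relabel_randomly(rng, jittered_copy(rng, ex4, 0.01))
        thr = IsoThresholds(epsilon=default_threshold(4), theta=default_threshold(4))
        assert min_pmval_oracle(ex4, other) <= thr.theta  # oracle confirms
        assert iso_test(ex4, other, thr).isomorphic

    def test_distinct_topologies_rejected_at_tight_thresholds(self, ex4, cycle4):
        assert min_pmval_oracle(ex4, cycle4) > 0.1
        v = iso_test(ex4, cycle4, IsoThresholds(epsilon=0.1, theta=0.1))
        assert not v.isomorphic

    def test_size_mismatch_short_circuits(self, ex4, triangle):
        v = iso_test(ex4, triangle, IsoThresholds(epsilon=10.0, theta=10.0))
        assert not v.isomorphic and v.stage == "size-mismatch"

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_relabeling_gives_zero_vmval(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, int(rng.integers(3, 6)), extra_edges=2)
        h, _ = relabel_randomly(rng, g)
        v = iso_test(g, h, IsoThresholds(epsilon=1e-9, theta=1e-9))
        assert v.isomorphic and v.vmval <= 1e-9

    def test_verdict_monotone_in_thresholds(self, ex4):
        rng = np.random.default_rng(5)
        other = jittered_copy(rng, ex4, 0.05)
        verdicts = [
            iso_test(ex4, other, IsoThresholds(epsilon=e, theta=t)).isomorphic
            for e, t in [(0.0, 0.0), (0.5, 0.5), (2.0, 2.0), (10.0, 10.0)]
        ]
        assert verdicts == sorted(verdicts)  # never flips true -> false

    def test_vmval_continuous_in_perturbation(self, ex4):
        rng = np.random.default_rng(7)
        vmvals = []
        for jit in (0.2, 0.05, 0.01, 0.001):
            other = jittered_copy(np.random.default_rng(7), ex4, jit)
            vmvals.append(iso_test(ex4, other, IsoThresholds(1e9, 1e9)).vmval)
        assert vmvals == sorted(vmvals, reverse=True) and vmvals[-1] < 1e-3

    def test_permutation_cap_raises(self, ex4, cycle4):
        thr = IsoThresholds(epsilon=1e9, theta=0.1, max_permutation_k=3)
        with pytest.raises(PermutationCapError):
            iso_test(ex4, cycle4, thr)

    @pytest.mark.parametrize("theta", [0.1, 0.5, 1.0])
    def test_agrees_with_exhaustive_oracle(self, theta):
        rng = np.random.default_rng(17)
        thr = IsoThresholds(epsilon=math.inf, theta=theta, augment=True)
        for _ in range(40):
            k = int(rng.integers(3, 6))
            ga = random_connected_graph(rng, k, extra_edges=2)
            if rng.uniform() < 0.5:
                gb, _ = relabel_randomly(rng, jittered_copy(rng, ga, 0.1))
                gb = ProbabilityGraph(
                    node_ids=[f"u{i}" for i in range(k)],
                    edges={e: p for e, p in gb.edges.items()},
                )
            else:
                gb = random_connected_graph(rng, k, extra_edges=1)
            expected = min_pmval_oracle(ga, gb) <= theta + 1e-9
            assert iso_test(ga, gb, thr).isomorphic == expected


class TestBruteForce:
    def test_self_is_isomorphic(self, ex4):
        ok, mapping, pm = brute_force_iso(ex4, ex4, alpha=0.0, theta=0.0)
        assert ok and pm == pytest.approx(0.0)

    def test_per_edge_alpha_violation_rejects(self):
        # best mapping has one edge differing by 0.15: fails alpha=0.1
        # even though the total stays below theta
        ga = ProbabilityGraph(
            node_ids=["a", "b", "c"],
            edges={("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5},
        )
        gb = ProbabilityGraph(
            node_ids=["x", "y", "z"],
            edges={("x", "y"): 0.5, ("y", "z"): 0.5, ("x", "z"): 0.65},
        )
        ok, _, pm = brute_force_iso(ga, gb, alpha=0.1, theta=5.0)
        assert not ok and pm == pytest.approx(0.3)
        ok2, _, _ = brute_force_iso(ga, gb, alpha=0.2, theta=5.0)
        assert ok2

    @pytest.mark.parametrize("seed", range(10))
    def test_theta_only_criterion_matches_iso_test(self, seed):
        rng = np.random.default_rng(seed)
        ga = random_connected_graph(rng, 4, extra_edges=2)
        gb = random_connected_graph(rng, 4, extra_edges=2)
        theta = float(rng.uniform(0.2, 2.0))
        ok, _, _ = brute_force_iso(ga, gb, alpha=1.0, theta=theta)
        thr = IsoThresholds(epsilon=math.inf, theta=theta)
        assert iso_test(ga, gb, thr).isomorphic == ok

    def test_large_k_refused(self):
        rng = np.random.default_rng(0)
        g = random_connected_graph(rng, 9, extra_edges=2)
        with pytest.raises(PermutationCapError):
            brute_force_iso(g, g, alpha=1.0, theta=1.0)
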