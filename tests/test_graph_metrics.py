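"""Weighted graph metrics, group comparison, behavioral correlation."""

import numpy as np
import pytest

from ptenet.graphs import (
    _distance_matrix,
    characteristic_path_length,
    compare_group_metrics,
    correlate_metrics_with_scores,
    global_efficiency,
    network_density,
    node_strength,
    small_worldness_propensity,
    subject_graph_metrics,
    swp_from_deltas,
)
from ptenet.stats import SignificantNetwork


def floyd_warshall(lengths):
    """Brute-force all-pairs shortest paths (independent oracle)."""
    n = lengths.shape[0]
    d = lengths.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def _random_weighted(rng, n, density=0.4):
    w = rng.uniform(0.2, 3.0, (n, n)) * (rng.uniform(size=(n, n)) < density)
    np.fill_diagonal(w, 0)
    return w


class TestNodeStrength:
    def test_star_graph(self):
        edges = [(0, i, 1.0) for i in range(1, 5)]
        net = SignificantNetwork(edges=edges, n_nodes_total=5)
        s = node_strength(net)
        assert s[0] == 4.0
        assert np.all(s[1:] == 1.0)

    def test_single_edge_counts_for_both_endpoints(self):
        net = SignificantNetwork(edges=[(0, 1, 3.0)], n_nodes_total=2)
        np.testing.assert_array_equal(node_strength(net), [3.0, 3.0])

    def test_empty_network(self):
        net = SignificantNetwork(edges=[], n_nodes_total=4)
        np.testing.assert_array_equal(node_strength(net, 4), np.zeros(4))


class TestDensity:
    @pytest.mark.parametrize(
        "n,e,expected", [(863, 892, 0.0024), (863, 441, 0.0012), (3, 3, 1.0)]
    )
    def test_worked_values(self, n, e, expected):
        assert network_density(n, e) == expected


class TestPathMetrics:
    def test_complete_unit_graph(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert global_efficiency(w) == pytest.approx(1.0)
        assert characteristic_path_length(w) == pytest.approx(1.0)

    def test_disconnected_efficiency_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_two_node_single_directed_edge(self):
        w = np.array([[0.0, 2.0], [0.0, 0.0]])
        assert global_efficiency(w) == pytest.approx(1.0)

    def test_three_node_chain_cpl(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert characteristic_path_length(w) == pytest.approx(4 / 3)

    def test_weight_scaling_homogeneity(self, rng):
        w = _random_weighted(rng, 8)
        base = characteristic_path_length(w)
        assert characteristic_path_length(3.0 * w) == pytest.approx(base / 3.0)

    def test_distances_match_floyd_warshall_battery(self, rng):
        for n in range(2, 11):
            for rep in range(4):
                w = _random_weighted(np.random.default_rng(100 * n + rep), n)
                with np.errstate(divide="ignore"):
                    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
                np.fill_diagonal(lengths, 0)
                np.testing.assert_allclose(
                    _distance_matrix(w), floyd_warshall(lengths), rtol=0, atol=1e-12
                )

    def test_adding_edge_never_decreases_efficiency(self, rng):
        w = _random_weighted(rng, 9)
        base = global_efficiency(w)
        zeros = np.argwhere((w == 0) & ~np.eye(9, dtype=bool))
        i, j = zeros[0]
        w2 = w.copy()
        w2[i, j] = 1.5
        assert global_efficiency(w2) >= base

    def test_no_edges_cpl_rejected(self):
        with pytest.raises(ValueError, match="no finite"):
            characteristic_path_length(np.zeros((3, 3)))


class TestSmallWorldPropensity:
    def test_analytic_delta_cases(self):
        assert swp_from_deltas(0, 0) == pytest.approx(1.0, abs=1e-12)
        assert swp_from_deltas(1, 1) == pytest.approx(0.0, abs=1e-12)
        assert swp_from_deltas(0, 1) == pytest.approx(1 - np.sqrt(0.5), abs=1e-12)
        # clipping: out-of-range deviations behave like the boundary
        assert swp_from_deltas(-3, 2) == swp_from_deltas(0, 1)

    def test_bounded_and_relabel_invariant(self, rng):
        import networkx as nx

        g = nx.watts_strogatz_graph(24, 6, 0.15, seed=3)
        w = nx.to_numpy_array(g) * rng.uniform(0.5, 1.5, (24, 24))
        w = np.maximum(w, w.T)
        s = small_worldness_propensity(w, seed=1, n_null=15)
        assert 0.0 <= s <= 1.0
        perm = rng.permutation(24)
        s_perm = small_worldness_propensity(w[np.ix_(perm, perm)], seed=1, n_null=15)
        assert s_perm == pytest.approx(s, abs=0.15)  # null draws differ

    def test_degenerate_nulls_rejected(self):
        w = np.ones((5, 5)) - np.eye(5)  # complete: lattice == random
        with pytest.raises(ValueError, match="degenerate"):
            small_worldness_propensity(w, seed=0)


@pytest.fixture(scope="module")
def mask_and_weights():
    rng = np.random.default_rng(5)
    import networkx as nx

    g = nx.watts_strogatz_graph(16, 4, 0.2, seed=2)
    mask = nx.to_numpy_array(g).astype(bool)
    w = rng.normal(1.0, 0.3, (16, 16))
    np.fill_diagonal(w, 0)
    return mask, w


class TestSubjectGraphMetrics:
    def test_identical_subjects_identical_records(self, mask_and_weights):
        mask, w = mask_and_weights
        a = subject_graph_metrics(w, mask, seed=3)
        b = subject_graph_metrics(w.copy(), mask, seed=3)
        assert a.swp == b.swp and a.efficiency == b.efficiency and a.cpl == b.cpl

    def test_contract_finite_and_bounded(self, mask_and_weights):
        mask, w = mask_and_weights
        gm = subject_graph_metrics(w, mask, seed=1)
        assert 0 <= gm.swp <= 1
        assert np.isfinite(gm.efficiency) and gm.efficiency >= 0
        assert np.isfinite(gm.cpl) and gm.cpl >= 0
        assert np.all(gm.strengths >= 0)

    def test_empty_mask_rejected(self, mask_and_weights):
        _, w = mask_and_weights
        with pytest.raises(ValueError, match="empty"):
            subject_graph_metrics(w, np.zeros_like(w, dtype=bool))


class TestGroupComparisonAndCorrelation:
    def test_exact_mann_whitney_worked_example(self):
        # {1,2,3} vs {4,5,6}: 2 of the C(6,3)=20 label arrangements are as
        # extreme, so the exact two-sided p is 0.1
        c = compare_group_metrics([1, 2, 3], [4, 5, 6])
        assert c.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_central_u(self):
        c = compare_group_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.u == pytest.approx(4.5)  # n1*n2/2

    def test_monotone_transform_preserves_p(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 12)
        c1 = compare_group_metrics(a, b)
        c2 = compare_group_metrics(np.exp(a), np.exp(b))
        assert c1.p == pytest.approx(c2.p, abs=1e-12)
        assert c1.u == c2.u

    def test_perfect_linear_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = correlate_metrics_with_scores(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed_negative_correlation(self):
        r, _ = correlate_metrics_with_scores(np.array([1, 2, 3]), np.array([6, 4, 5]))
        assert r == pytest.approx(-0.5, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_metrics_with_scores(np.ones(5), np.arange(5.0))

    def test_group_order_swap_mirrors_comparison(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        c1 = compare_group_metrics(a, b)
        c2 = compare_group_metrics(b, a)
        assert c1.p == pytest.approx(c2.p, abs=1e-12)
        assert c1.u_standardized == pytest.approx(-c2.u_standardized, abs=1e-12)
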