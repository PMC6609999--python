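"""FD graphs: thresholding schemes and topology features.

networkx serves as the independent oracle for the feature definitions; the
implementation itself works directly on the adjacency matrix.
"""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kcdetect.graph import (
    AdjacencyMatrix,
    calibrate_threshold,
    clustering_coefficients,
    degree_distribution,
    distance_matrix,
    graph_feature_vector,
    jaccard_coefficients,
    mst_adjacency,
    threshold_adjacency,
)

# illustrative FD-style vector with one far outlier
OUTLIER_VECTOR = np.array([1.2, 1.4, 1.3, 0.7, 1.9, 2.2, 0.3, 2.0, 2.8, 4.6, 12.2])


def adjacency_from_edges(n, edges):
    B = np.zeros((n, n), dtype=int)
    for i, j in edges:
        B[i, j] = B[j, i] = 1
    return AdjacencyMatrix(B=B)


FOUR_CYCLE = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
STAR = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
TRIANGLE = adjacency_from_edges(3, [(0, 1), (1, 2), (2, 0)])
K4 = adjacency_from_edges(4, list(combinations(range(4), 2)))


class TestDistanceMatrix:
    def test_equal_values_give_zero_matrix(self):
        d = distance_matrix(np.ones(5))
        assert np.all(d.d == 0)

    def test_scalar_euclidean_distance(self):
        d = distance_matrix(np.array([1.2, 1.4]))
        assert d.d[0, 1] == pytest.approx(0.2)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        d = distance_matrix(rng.random(10))
        np.testing.assert_allclose(d.d, d.d.T)
        assert np.all(np.diag(d.d) == 0)


class TestThresholdAdjacency:
    def test_saturation_gives_complete_graph(self):
        d = distance_matrix(OUTLIER_VECTOR)
        B = threshold_adjacency(d, d.d.max())
        assert B.degrees.tolist() == [10] * 11

    def test_zero_threshold_distinct_values(self):
        B = threshold_adjacency(distance_matrix(np.array([1.0, 2.0, 3.0])), 0.0)
        assert B.B.sum() == 0

    def test_outlier_node_isolated(self):
        # the far value 12.2 is >> thr away from everything else
        B = threshold_adjacency(distance_matrix(OUTLIER_VECTOR), 2.0)
        assert B.degrees[-1] == 0
        assert B.degrees[:-1].min() > 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_adjacency(distance_matrix(np.array([1.0, 2.0])), -0.1)


class TestCalibrateThreshold:
    def test_target_n_minus_1_complete(self):
        d = distance_matrix(OUTLIER_VECTOR)
        thr = calibrate_threshold(d, d.n - 1)
        assert thr == pytest.approx(d.d.max())
        assert threshold_adjacency(d, thr).mean_degree == d.n - 1

    def test_target_zero_empty_graph(self):
        d = distance_matrix(np.array([1.0, 1.5, 2.5]))
        thr = calibrate_threshold(d, 0)
        assert threshold_adjacency(d, thr).B.sum() == 0

    def test_exhaustive_scan_oracle(self):
        # oracle: evaluate the mean degree at every candidate threshold and
        # take the smallest one meeting the target
        rng = np.random.default_rng(42)
        values = rng.random(10) * 2
        d = distance_matrix(values)
        target = 6.0
        thr = calibrate_threshold(d, target)
        candidates = np.unique(d.d[~np.eye(10, dtype=bool)])
        meeting = [
            c for c in candidates
            if threshold_adjacency(d, c).mean_degree >= target
        ]
        assert thr == pytest.approx(min(meeting))
        achieved = threshold_adjacency(d, thr).mean_degree
        assert target <= achieved <= target + 2 / 10 + 1e-12

    def test_monotone_in_target(self):
        rng = np.random.default_rng(7)
        d = distance_matrix(rng.random(10))
        thrs = [calibrate_threshold(d, t) for t in range(0, 10)]
        assert all(a <= b for a, b in zip(thrs, thrs[1:]))

    def test_impossible_target(self):
        with pytest.raises(ValueError):
            calibrate_threshold(distance_matrix(np.arange(5.0)), 5)


class TestMST:
    def test_tree_properties(self):
        rng = np.random.default_rng(3)
        d = distance_matrix(rng.random(10))
        B = mst_adjacency(d)
        assert B.B.sum() // 2 == 9
        assert nx.is_connected(nx.from_numpy_array(B.B))

    def test_chain_on_line_values(self):
        # Kruskal by hand on values 1, 2, 4, 8: edges 1-2, 2-4, 4-8
        B = mst_adjacency(distance_matrix(np.array([1.0, 2.0, 4.0, 8.0])))
        expected = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        np.testing.assert_array_equal(B.B, expected.B)

    def test_single_node(self):
        B = mst_adjacency(distance_matrix(np.array([1.0])))
        assert B.B.sum() == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_weight_matches_bruteforce_enumeration(self, seed):
        # brute force: enumerate all spanning trees of K_n via edge subsets
        rng = np.random.default_rng(seed)
        n = 6
        values = rng.random(n) * 3
        d = distance_matrix(values)
        B = mst_adjacency(d)
        got = (B.B * d.d).sum() / 2
        all_edges = list(combinations(range(n), 2))
        best = np.inf
        for subset in combinations(all_edges, n - 1):
            G = nx.Graph(subset)
            if G.number_of_nodes() == n and nx.is_connected(G):
                w = sum(d.d[i, j] for i, j in subset)
                best = min(best, w)
        assert got == pytest.approx(best)


class TestDegreeDistribution:
    def test_complete_graph(self):
        P = degree_distribution(K4)
        assert P[3] == 1.0 and P[:3].sum() == 0

    def test_counting_rule(self):
        # 10-node graph where exactly 3 nodes have degree 1
        B = adjacency_from_edges(10, [(0, 1), (2, 3), (3, 4), (4, 2), (5, 4)])
        P = degree_distribution(B)
        degs = B.degrees
        k1 = int(np.sum(degs == 1))
        assert k1 == 3
        assert P[1] == pytest.approx(3 / 10)

    def test_empty_graph(self):
        B = adjacency_from_edges(5, [])
        P = degree_distribution(B)
        assert P[0] == 1.0

    def test_networkx_oracle(self):
        rng = np.random.default_rng(11)
        B = threshold_adjacency(distance_matrix(rng.random(10)), 0.3)
        G = nx.from_numpy_array(B.B)
        hist = np.array(nx.degree_histogram(G), dtype=float)
        hist = np.pad(hist, (0, 10 - len(hist))) / 10
        np.testing.assert_allclose(degree_distribution(B), hist)


class TestClusteringCoefficients:
    def test_triangle_is_fully_clustered(self):
        per_node, mean = clustering_coefficients(TRIANGLE)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == 1.0

    def test_star_has_no_triangles(self):
        per_node, mean = clustering_coefficients(STAR)
        np.testing.assert_allclose(per_node, 0.0)
        assert mean == 0.0

    def test_fully_connected_neighbourhood(self):
        # node 0's neighbours {1, 2, 3} pairwise connected -> CC(0) = 1
        per_node, _ = clustering_coefficients(K4)
        assert per_node[0] == 1.0

    def test_networkx_oracle(self):
        rng = np.random.default_rng(13)
        B = threshold_adjacency(distance_matrix(rng.random(10)), 0.25)
        per_node, mean = clustering_coefficients(B)
        expected = nx.clustering(nx.from_numpy_array(B.B))
        np.testing.assert_allclose(per_node, [expected[i] for i in range(10)])


class TestJaccardCoefficients:
    def test_four_cycle_hand_enumeration(self):
        # opposite nodes share both neighbours (M = 1); adjacent nodes have
        # disjoint neighbourhoods (M = 0)
        pairs, mean = jaccard_coefficients(FOUR_CYCLE)
        # pair order: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        np.testing.assert_allclose(pairs, [0, 1, 0, 0, 1, 0])
        assert mean == pytest.approx(2 / 6)

    def test_identical_neighbourhoods(self):
        pairs, _ = jaccard_coefficients(STAR)
        # leaves 1,2,3 all have neighbourhood {0}
        assert pairs[3] == 1.0 and pairs[4] == 1.0 and pairs[5] == 1.0

    def test_empty_graph_all_zero(self):
        pairs, mean = jaccard_coefficients(adjacency_from_edges(4, []))
        np.testing.assert_allclose(pairs, 0.0)
        assert mean == 0.0

    def test_networkx_oracle(self):
        rng = np.random.default_rng(17)
        B = threshold_adjacency(distance_matrix(rng.random(10)), 0.3)
        pairs, _ = jaccard_coefficients(B)
        G = nx.from_numpy_array(B.B)
        expected = {(u, v): p for u, v, p in nx.jaccard_coefficient(
            G, combinations(range(10), 2))}
        got = dict(zip(combinations(range(10), 2), pairs))
        for key in expected:
            assert got[key] == pytest.approx(expected[key])


class TestGraphFeatureVector:
    def test_complete_graph_scalars(self):
        B = adjacency_from_edges(10, list(combinations(range(10), 2)))
        vec = graph_feature_vector(B)
        assert vec[9] == 1.0  # P(9)
        assert vec[10] == 1.0  # mean CC
        # open neighbourhoods: |V \ {i,j}| / |V| = 8/10 for every clique pair
        assert vec[11] == pytest.approx(0.8)

    def test_empty_graph_scalars(self):
        vec = graph_feature_vector(adjacency_from_edges(10, []))
        assert vec[0] == 1.0
        assert vec[10] == 0.0 and vec[11] == 0.0

    def test_lengths(self):
        rng = np.random.default_rng(23)
        B = threshold_adjacency(distance_matrix(rng.random(10)), 0.2)
        assert len(graph_feature_vector(B, "scalar")) == 12
        assert len(graph_feature_vector(B, "full")) == 12 + 45


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 100_000), st.floats(0, 1))
def test_feature_invariants_random_graphs(seed, thr):
    """Symmetry, distribution normalisation and [0, 1] feature bounds."""
    rng = np.random.default_rng(seed)
    B = threshold_adjacency(distance_matrix(rng.random(10) * 2), thr)
    np.testing.assert_array_equal(B.B, B.B.T)
    assert np.all(np.diag(B.B) == 0)
    assert degree_distribution(B).sum() == pytest.approx(1.0, abs=1e-12)
    per_node, mean_cc = clustering_coefficients(B)
    pairs, mean_j = jaccard_coefficients(B)
    assert np.all((per_node >= 0) & (per_node <= 1))
    assert 0 <= mean_cc <= 1 and 0 <= mean_j <= 1
    assert np.all((pairs >= 0) & (pairs <= 1))
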