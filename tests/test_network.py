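"""PLI and graph-metric tests against hand enumeration and brute-force
oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megconsist import (
    AdjacencyMatrix,
    instantaneous_phase,
    minimum_spanning_tree,
    modularity,
    mst_metrics,
    network_metrics,
    newman_q,
    pli,
    pli_adjacency,
    weighted_clustering,
    weighted_path_length,
)

FS = 625.0


def random_adjacency(r, rng, zero_frac=0.0):
    w = rng.uniform(0.05, 1.0, size=(r, r))
    w = np.triu(w, 1)
    if zero_frac:
        mask = np.triu(rng.random((r, r)) < zero_frac, 1)
        w[mask] = 0.0
    w = w + w.T
    return w


class TestInstantaneousPhase:
    def test_cosine_phase_advances_at_carrier_rate(self):
        t = np.arange(4096) / FS
        ph = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        slope = np.diff(np.unwrap(ph))[100:-100].mean() * FS
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_sin_vs_cos_quarter_cycle(self):
        # 5000 samples = integer cycle count at 10 Hz: no leakage at the edges
        t = np.arange(5000) / FS
        d = instantaneous_phase(np.cos(2 * np.pi * 10 * t)) - instantaneous_phase(
            np.sin(2 * np.pi * 10 * t)
        )
        d = np.angle(np.exp(1j * d))[200:-200]
        assert np.allclose(d, np.pi / 2, atol=0.01)

    def test_amplitude_invariance(self, rng):
        x = np.cos(2 * np.pi * 8 * np.arange(1024) / FS)
        assert np.allclose(instantaneous_phase(3.7 * x), instantaneous_phase(x))

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="no oscillation"):
            instantaneous_phase(np.ones(100))


class TestPLI:
    def test_constant_lag_is_one(self):
        assert pli(np.full(1000, np.pi / 4)) == 1.0

    def test_symmetric_lag_mixture_is_zero(self):
        d = np.tile([np.pi / 4, -np.pi / 4], 500)
        assert pli(d) == pytest.approx(0.0, abs=1e-12)

    def test_zero_lag_is_zero(self):
        # volume conduction produces exactly zero phase difference
        assert pli(np.zeros(1000)) == 0.0

    def test_uniform_null_small(self):
        vals = [
            pli(np.random.default_rng(s).uniform(-np.pi, np.pi, 10_000))
            for s in range(200)
        ]
        assert np.quantile(vals, 0.99) <= 0.04

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 500), k=st.integers(-3, 3))
    def test_invariances(self, seed, k):
        d = np.random.default_rng(seed).uniform(-np.pi, np.pi, 512)
        v = pli(d)
        assert 0.0 <= v <= 1.0
        assert pli(-d) == pytest.approx(v, abs=1e-12)          # swap signals
        assert pli(d + 2 * np.pi * k) == pytest.approx(v, abs=1e-9)


class TestPliAdjacency:
    def test_constant_lag_pair_saturates(self):
        t = np.arange(4096) / FS
        x = np.cos(2 * np.pi * 9 * t)
        y = np.cos(2 * np.pi * 9 * t - np.pi / 4)
        adj = pli_adjacency(np.stack([x, y]))
        assert adj.weights[0, 1] > 0.99
        assert adj.weights[0, 0] == 0.0

    def test_permutation_equivariance(self, rng):
        x = rng.standard_normal((4, 1024))
        from megconsist import bandpass_fft
        from megconsist.bands import band_by_name

        x = bandpass_fft(x, band_by_name("alpha1"), FS)
        perm = np.array([2, 0, 3, 1])
        a = pli_adjacency(x).weights
        b = pli_adjacency(x[perm]).weights
        assert np.allclose(b, a[np.ix_(perm, perm)], atol=1e-12)

    def test_global_mean_invariant_under_relabeling(self, rng):
        w = random_adjacency(6, rng)
        adj = AdjacencyMatrix(w)
        perm = rng.permutation(6)
        adj_p = AdjacencyMatrix(w[np.ix_(perm, perm)])
        assert adj.global_mean() == pytest.approx(adj_p.global_mean())


class TestWeightedClustering:
    def test_perfect_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert weighted_clustering(w) == pytest.approx(1.0)

    def test_open_path_has_no_clustering(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert weighted_clustering(w) == 0.0

    def test_uniform_half_triangle(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0)
        assert weighted_clustering(w) == pytest.approx(0.5)

    def test_bounded_by_unit_interval(self, rng):
        for _ in range(20):
            w = random_adjacency(7, rng, zero_frac=0.3)
            assert 0.0 <= weighted_clustering(w) <= 1.0


class TestWeightedPathLength:
    def test_single_edge(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert weighted_path_length(w) == pytest.approx(2.0)

    def test_unit_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert weighted_path_length(w) == pytest.approx(1.0)

    def test_indirect_route_wins(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.1
        assert weighted_path_length(w) == pytest.approx(2.0)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(20):
            r = int(rng.integers(3, 8))
            w = random_adjacency(r, rng, zero_frac=0.2)
            if not np.all(_floyd(w) < np.inf):
                continue
            assert weighted_path_length(w) == pytest.approx(
                _floyd(w)[~np.eye(r, dtype=bool)].mean(), rel=1e-10
            )


def _floyd(w):
    r = w.shape[0]
    d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(r):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def enumerate_partitions(n):
    """All set partitions of range(n) as label arrays (Bell-number many)."""
    if n == 1:
        yield np.zeros(1, int)
        return
    for sub in enumerate_partitions(n - 1):
        k = sub.max() + 1
        for c in range(k + 1):
            yield np.append(sub, c)


class TestModularity:
    def test_single_module_partition_scores_zero(self, rng):
        w = random_adjacency(6, rng)
        assert newman_q(w, np.zeros(6, int)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_exact(self):
        w = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.permutations(grp, 2):
                w[i, j] = 1.0
        # exact enumeration oracle over all partitions of 6 nodes
        best = max(newman_q(w, np.array(p)) for p in enumerate_partitions(6))
        assert best == pytest.approx(0.5)
        q, n_mod = modularity(w, n_runs=20, seed=3)
        assert q == pytest.approx(0.5, abs=1e-9)
        assert n_mod == pytest.approx(2.0)

    def test_annealed_q_between_zero_and_exact_max(self, rng):
        w = random_adjacency(6, rng, zero_frac=0.4)
        exact = max(newman_q(w, np.array(p)) for p in enumerate_partitions(6))
        q, _ = modularity(w, n_runs=10, seed=0)
        assert 0.0 <= q <= exact + 1e-9
        assert q <= 1.0

    def test_deterministic_per_seed(self, rng):
        w = random_adjacency(8, rng)
        assert modularity(w, n_runs=5, seed=7) == modularity(w, n_runs=5, seed=7)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError, match="empty graph"):
            modularity(np.zeros((4, 4)), n_runs=1, seed=0)


class TestMST:
    def test_triangle_keeps_two_strongest(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.4
        tree = minimum_spanning_tree(w)
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]

    def test_tree_input_is_fixed_point(self, rng):
        # a path graph is its own unique spanning tree
        r = 6
        w = np.zeros((r, r))
        for i in range(r - 1):
            w[i, i + 1] = w[i + 1, i] = rng.uniform(0.2, 1.0)
        tree = minimum_spanning_tree(w)
        assert sorted((i, j) for i, j, _ in tree.edges) == [(i, i + 1) for i in range(r - 1)]

    def test_matches_scipy_total_length(self, rng):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst

        for _ in range(20):
            r = int(rng.integers(4, 9))
            w = random_adjacency(r, rng)
            tree = minimum_spanning_tree(w)
            mine = sum(1.0 / wt for _, _, wt in tree.edges)
            ref = scipy_mst(csr_matrix(1.0 / w)).sum()
            assert mine == pytest.approx(ref, rel=1e-10)

    def test_disconnected_raises(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(ValueError, match="disconnected"):
            minimum_spanning_tree(w)

    def test_degree_sum_and_leaf_bound(self, rng):
        for _ in range(10):
            r = int(rng.integers(3, 10))
            tree = minimum_spanning_tree(random_adjacency(r, rng))
            deg, leaf, diam = mst_metrics(tree)
            assert deg.sum() == 2 * (r - 1)
            assert leaf >= 2 / r
            assert 1 <= diam <= r - 1


class TestMSTMetrics:
    def test_path_of_five(self):
        from megconsist import SpanningTree

        tree = SpanningTree([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0)], 5)
        deg, leaf, diam = mst_metrics(tree)
        assert list(deg) == [1, 2, 2, 2, 1]
        assert leaf == pytest.approx(0.4)
        assert diam == 4

    def test_star_of_five(self):
        from megconsist import SpanningTree

        tree = SpanningTree([(0, i, 1.0) for i in range(1, 5)], 5)
        _, leaf, diam = mst_metrics(tree)
        assert leaf == pytest.approx(0.8)
        assert diam == 2

    def test_diameter_matches_all_pairs_bfs_oracle(self, rng):
        import networkx as nx

        for _ in range(15):
            r = int(rng.integers(3, 9))
            g = nx.random_labeled_tree(r, seed=int(rng.integers(1 << 30)))
            edges = [(u, v, 1.0) for u, v in g.edges]
            from megconsist import SpanningTree

            _, _, diam = mst_metrics(SpanningTree(edges, r))
            assert diam == nx.diameter(g)


class TestNetworkMetricsBundle:
    def test_bundle_is_consistent_with_parts(self, rng):
        w = random_adjacency(8, rng)
        nm = network_metrics(w, modularity_runs=3, seed=5)
        assert nm.cw == pytest.approx(weighted_clustering(w))
        assert nm.lw == pytest.approx(weighted_path_length(w))
        deg, leaf, diam = mst_metrics(minimum_spanning_tree(w))
        assert np.array_equal(nm.mst_degree, deg)
        assert nm.leaf_fraction == leaf and nm.diameter == diam
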