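import numpy as np
import pytest

from tpenet import atlas
from tpenet.graphs import (
    BinaryGraph, DEFAULT_SPARSITY_GRID, global_metrics, graph_feature_profile,
    nodal_metrics, random_reference_graph, small_world_indices,
    threshold_by_sparsity, _trapezoid_mean,
)
from tpenet.metabolic import IndividualNetwork

from oracles import brute_graph_metrics


def net_from(W):
    n = W.shape[0]
    labels = list(atlas.REGION_LABELS)[:n]
    return IndividualNetwork(W=W, subject_id="toy", region_labels=labels)


def graph_from(A, sparsity=0.5):
    return BinaryGraph(adjacency=np.asarray(A, dtype=np.int8), sparsity=sparsity)


def complete(n):
    A = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(A, 0)
    return A


class TestThreshold:
    def test_edge_count_law_across_grid(self, nc_reference):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((56, 56))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        for s in DEFAULT_SPARSITY_GRID:
            g = threshold_by_sparsity(net_from(W), s)
            assert g.n_edges == round(s * 1540)

    def test_known_top_edges_selected(self):
        rng = np.random.default_rng(1)
        W = 0.1 * rng.random((56, 56))
        W = (W + W.T) / 2
        top = [(0, 5), (3, 9), (10, 11), (2, 40), (33, 50)]
        for i, j in top:
            W[i, j] = W[j, i] = 1.0 + i * 0.01
        np.fill_diagonal(W, 0)
        g = threshold_by_sparsity(net_from(W), 5 / 1540)
        got = set(zip(*np.nonzero(np.triu(g.adjacency))))
        assert got == set(top)

    def test_absolute_weight_ranking(self):
        W = np.zeros((56, 56))
        W[0, 1] = W[1, 0] = -0.9  # strongest by magnitude, negative sign
        W[2, 3] = W[3, 2] = 0.5
        g = threshold_by_sparsity(net_from(W), 1 / 1540)
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 0

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError):
            threshold_by_sparsity(net_from(np.zeros((56, 56))), 1.5)

    def test_nested_e_global_monotone_in_sparsity(self, nc_reference):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((56, 56))
        W = (W + W.T) / 2
        vals = []
        for s in DEFAULT_SPARSITY_GRID:
            g = threshold_by_sparsity(net_from(W), s)
            vals.append(global_metrics(g)[2])
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestNodalMetrics:
    def test_complete_graph(self):
        g = graph_from(complete(5))
        dc, ncf = nodal_metrics(g, [0])
        assert dc[0] == 4 and ncf[0] == pytest.approx(1.0)

    def test_star_center_has_no_triangles(self):
        A = np.zeros((6, 6), dtype=np.int8)
        A[0, 1:] = A[1:, 0] = 1
        dc, ncf = nodal_metrics(graph_from(A), [0])
        assert dc[0] == 5 and ncf[0] == 0.0

    def test_triangle_with_pendant(self):
        A = np.zeros((4, 4), dtype=np.int8)
        for i, j in [(0, 1), (1, 2), (0, 2), (0, 3)]:
            A[i, j] = A[j, i] = 1
        dc, ncf = nodal_metrics(graph_from(A), [0])
        assert dc[0] == 3 and ncf[0] == pytest.approx(1 / 3)


class TestGlobalMetrics:
    def test_complete_graph_all_ones(self):
        c, l, eg, el = global_metrics(graph_from(complete(10)))
        assert (c, l, eg, el) == (1.0, 1.0, 1.0, 1.0)

    def test_path_of_three(self):
        A = np.zeros((3, 3), dtype=np.int8)
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        _, _, eg, _ = global_metrics(graph_from(A))
        assert eg == pytest.approx(5 / 6)

    def test_two_disjoint_edges(self):
        A = np.zeros((4, 4), dtype=np.int8)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        c, l, eg, el = global_metrics(graph_from(A))
        assert eg == pytest.approx(1 / 3)
        assert l == pytest.approx(1.0)  # connected pairs only

    def test_oracle_equivalence_on_random_small_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            A = (rng.random((n, n)) < rng.uniform(0.2, 0.7)).astype(np.int8)
            A = np.triu(A, 1)
            A = A + A.T
            g = graph_from(A)
            c, l, eg, el = global_metrics(g)
            ref = brute_graph_metrics(A)
            assert c == pytest.approx(ref["c_mean"], abs=1e-12)
            assert eg == pytest.approx(ref["e_global"], abs=1e-12)
            assert el == pytest.approx(ref["e_local"], abs=1e-12)
            if np.isfinite(ref["l_char"]):
                assert l == pytest.approx(ref["l_char"], abs=1e-12)
            dc, ncf = nodal_metrics(g, list(range(n)))
            for i in range(n):
                assert dc[i] == ref["degree"][i]
                assert ncf[i] == pytest.approx(ref["clustering"][i], abs=1e-12)


class TestRandomReference:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(4)
        A = (rng.random((56, 56)) < 0.3).astype(np.int8)
        A = np.triu(A, 1); A = A + A.T
        g = graph_from(A)
        r = random_reference_graph(g, seed=0)
        assert np.array_equal(r.adjacency.sum(0), g.adjacency.sum(0))
        assert not np.array_equal(r.adjacency, g.adjacency)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        A = (rng.random((30, 30)) < 0.3).astype(np.int8)
        A = np.triu(A, 1); A = A + A.T
        g = graph_from(A)
        r1 = random_reference_graph(g, seed=11)
        r2 = random_reference_graph(g, seed=11)
        assert np.array_equal(r1.adjacency, r2.adjacency)

    def test_ring_lattice_clustering_decays_toward_er(self):
        n, k = 56, 4
        A = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                A[i, (i + d) % n] = A[(i + d) % n, i] = 1
        g = graph_from(A)
        c0 = global_metrics(g)[0]  # ring lattice k=4 -> C = 0.5
        r = random_reference_graph(g, seed=1)
        c1 = global_metrics(r)[0]
        er = k / (n - 1)
        assert c0 == pytest.approx(0.5)
        assert c1 < 0.25 and abs(c1 - er) < 0.15


class TestSmallWorld:
    def test_er_graph_self_normalizes_to_one(self):
        rng = np.random.default_rng(6)
        A = (rng.random((56, 56)) < 0.3).astype(np.int8)
        A = np.triu(A, 1); A = A + A.T
        gamma, lam, sigma = small_world_indices(graph_from(A), n_rand=50, seed=0)
        assert abs(gamma - 1) < 0.15 and abs(lam - 1) < 0.15 and abs(sigma - 1) < 0.15

    def test_watts_strogatz_is_small_world(self):
        import networkx as nx

        G = nx.connected_watts_strogatz_graph(56, 10, 0.1, seed=3)
        A = nx.to_numpy_array(G).astype(np.int8)
        gamma, lam, sigma = small_world_indices(graph_from(A), n_rand=30, seed=0)
        assert sigma > 1.0

    def test_complete_graph_is_its_own_reference(self):
        g = graph_from(complete(12))
        gamma, lam, sigma = small_world_indices(g, n_rand=5, seed=0)
        assert gamma == 1.0 and lam == 1.0 and sigma == 1.0


class TestFeatureProfile:
    def test_constant_metric_aggregates_to_itself(self):
        x = np.asarray(DEFAULT_SPARSITY_GRID)
        assert _trapezoid_mean(x, np.full(x.size, 3.7)) == pytest.approx(3.7)

    def test_default_grid_has_ten_points(self):
        assert len(DEFAULT_SPARSITY_GRID) == 10
        assert DEFAULT_SPARSITY_GRID[0] == 0.20
        assert DEFAULT_SPARSITY_GRID[-1] == 0.65

    def test_aggregated_e_global_matches_per_sparsity_enumeration(self, nc_reference):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((56, 56))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        net = net_from(W)
        fs, curves = graph_feature_profile(
            net, n_rand=3, seed=0, return_curves=True
        )
        expect = []
        for s in DEFAULT_SPARSITY_GRID:
            A = threshold_by_sparsity(net, s).adjacency
            expect.append(brute_graph_metrics(A)["e_global"])
        assert np.allclose(curves["e_global"], expect, atol=1e-12)
        x = np.asarray(DEFAULT_SPARSITY_GRID)
        assert fs.e_global == pytest.approx(
            np.trapezoid(expect, x) / (x[-1] - x[0])
        )

    def test_insula_nodes_resolved_by_label(self, nc_reference):
        rng = np.random.default_rng(8)
        W = rng.standard_normal((56, 56)); W = (W + W.T) / 2
        net = net_from(W)
        bad = IndividualNetwork(W=W, subject_id="x",
                                region_labels=[f"r{i}" for i in range(56)])
        with pytest.raises(ValueError, match="insula"):
            graph_feature_profile(bad, n_rand=2, seed=0)
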