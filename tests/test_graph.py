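"""Graph-metric tests: worked examples, brute-force oracles,
permutation invariance and threshold-sweep monotonicity."""

import networkx as nx
import numpy as np
import pytest

from wbnet import (
    AdjacencyMatrix,
    characteristic_path_length,
    clustering,
    compute_metrics,
    count_connected_nodes,
    degrees,
    global_efficiency,
    make_canonical_graph,
    metrics_table,
    node_strength,
    random_reference,
    small_world_index,
    threshold_adjacency,
    threshold_grid,
)
from wbnet.graph import UndefinedMetricError


# ------------------------------------------------------------- oracles


def brute_force_distances(a: np.ndarray) -> np.ndarray:
    """Floyd-Warshall by explicit triple loop."""
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_force_metrics(a: np.ndarray) -> dict:
    """Degree, path length, clustering and efficiency by enumeration."""
    n = a.shape[0]
    deg = a.sum(axis=1)
    d = brute_force_distances(a)
    finite, inv_sum, n_reach, n_unreach = [], 0.0, 0, 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                finite.append(d[i, j])
                inv_sum += 1.0 / d[i, j]
                n_reach += 1
            else:
                n_unreach += 1
    cc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k >= 2:
            e = sum(
                a[u, v] for x, u in enumerate(nbrs) for v in nbrs[x + 1 :]
            )
            cc[i] = 2.0 * e / (k * (k - 1))
    return {
        "D": deg.mean(),
        "L": np.mean(finite) if finite else np.nan,
        "unreachable": n_unreach,
        "CC": cc.mean(),
        "E": inv_sum / (n * (n - 1)),
    }


def random_adjacency(n: int, p: float, rng) -> AdjacencyMatrix:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return AdjacencyMatrix(a=a + a.T)


# ------------------------------------------------------------ threshold


class TestThreshold:
    def test_inclusive_rule_on_worked_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.10
        w[0, 2] = w[2, 0] = 0.22
        w[1, 2] = w[2, 1] = 0.30
        adj = threshold_adjacency(w, 0.22)
        assert adj.n_edges == 2
        assert adj.a[0, 2] == 1 and adj.a[1, 2] == 1 and adj.a[0, 1] == 0

    def test_zero_threshold_complete(self):
        w = np.random.default_rng(0).uniform(0.1, 1, (5, 5))
        w = (w + w.T) / 2
        adj = threshold_adjacency(w, 0.0)
        assert adj.n_edges == 10
        assert np.all(np.diag(adj.a) == 0)

    def test_above_max_gives_edgeless(self):
        w = np.full((4, 4), 0.5)
        adj = threshold_adjacency(w, 0.51)
        assert adj.n_edges == 0

    def test_grid_defaults_give_51(self):
        g = threshold_grid()
        assert len(g) == 51
        assert g[0] == 0.0
        assert g[-1] == pytest.approx(0.5)

    def test_grid_edge_cases(self):
        np.testing.assert_allclose(threshold_grid(0, 0, 0.01), [0])
        np.testing.assert_allclose(threshold_grid(0, 0.1, 0.05), [0, 0.05, 0.1])


class TestBasicMetrics:
    def test_node_strength_worked_examples(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.2
        w[1, 2] = w[2, 1] = 0.1
        np.testing.assert_allclose(node_strength(w), [0.7, 0.6, 0.3])
        np.testing.assert_array_equal(node_strength(np.zeros((3, 3))), 0.0)
        uniform = np.full((6, 6), 0.3)
        np.testing.assert_allclose(node_strength(uniform), 5 * 0.3)

    def test_degrees_complete_68(self):
        adj = make_canonical_graph("complete", 68)
        d, avg = degrees(adj)
        assert np.all(d == 67)
        assert avg == 67.0

    def test_degrees_path_graph(self):
        adj = make_canonical_graph("path", 3)
        d, avg = degrees(adj)
        np.testing.assert_array_equal(sorted(d), [1, 1, 2])
        assert avg == pytest.approx(4 / 3)

    def test_path_length_examples(self):
        assert characteristic_path_length(make_canonical_graph("complete", 10)).L == 1.0
        pl = characteristic_path_length(make_canonical_graph("path", 3))
        assert pl.L == pytest.approx(4 / 3)
        assert pl.unreachable_pairs == 0
        # two disjoint edges on 4 nodes
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        pl = characteristic_path_length(AdjacencyMatrix(a=a))
        assert pl.L == 1.0
        assert pl.unreachable_pairs == 8

    def test_path_length_undefined_without_edges(self):
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(AdjacencyMatrix(a=np.zeros((4, 4), dtype=int)))

    def test_clustering_examples(self):
        tri = AdjacencyMatrix(a=np.ones((3, 3), dtype=int) - np.eye(3, dtype=int))
        cc_i, cc = clustering(tri)
        np.testing.assert_array_equal(cc_i, 1.0)
        assert cc == 1.0
        star = make_canonical_graph("star", 4)
        cc_i, cc = clustering(star)
        np.testing.assert_array_equal(cc_i, 0.0)
        assert clustering(make_canonical_graph("complete", 7))[1] == 1.0

    def test_efficiency_examples(self):
        assert global_efficiency(make_canonical_graph("complete", 9)) == 1.0
        assert global_efficiency(AdjacencyMatrix(a=np.zeros((4, 4), dtype=int))) == 0.0
        assert global_efficiency(make_canonical_graph("path", 3)) == pytest.approx(5 / 6)

    def test_count_connected_nodes(self):
        assert count_connected_nodes(make_canonical_graph("complete", 68)) == 68
        assert count_connected_nodes(AdjacencyMatrix(a=np.zeros((5, 5), dtype=int))) == 0
        one_edge = np.zeros((5, 5), dtype=int)
        one_edge[0, 1] = one_edge[1, 0] = 1
        assert count_connected_nodes(AdjacencyMatrix(a=one_edge)) == 2


class TestOracleAgreement:
    @pytest.mark.parametrize("n,p,seed", [(5, 0.4, 1), (7, 0.3, 2), (7, 0.6, 3),
                                          (8, 0.25, 4), (8, 0.5, 5), (6, 0.9, 6)])
    def test_matches_brute_force(self, n, p, seed):
        adj = random_adjacency(n, p, np.random.default_rng(seed))
        ref = brute_force_metrics(adj.a)
        _, avg = degrees(adj)
        assert avg == pytest.approx(ref["D"], abs=1e-12)
        assert clustering(adj)[1] == pytest.approx(ref["CC"], abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(ref["E"], abs=1e-12)
        if adj.n_edges:
            pl = characteristic_path_length(adj)
            assert pl.L == pytest.approx(ref["L"], abs=1e-12)
            assert pl.unreachable_pairs == ref["unreachable"]

    def test_matches_networkx_on_connected_graph(self):
        adj = make_canonical_graph("watts_strogatz", 30, seed=0, k=4, p=0.2)
        g = nx.from_numpy_array(adj.a)
        cc_i, cc = clustering(adj)
        nx_cc = nx.clustering(g)
        np.testing.assert_allclose(cc_i, [nx_cc[i] for i in range(30)], atol=1e-12)
        if nx.is_connected(g):
            assert characteristic_path_length(adj).L == pytest.approx(
                nx.average_shortest_path_length(g), abs=1e-12
            )
        assert global_efficiency(adj) == pytest.approx(
            nx.global_efficiency(g), abs=1e-12
        )


class TestPermutationInvariance:
    def test_scalar_metrics_permutation_invariant(self):
        rng = np.random.default_rng(12)
        adj = random_adjacency(9, 0.35, rng)
        perm = rng.permutation(9)
        padj = AdjacencyMatrix(a=adj.a[np.ix_(perm, perm)])
        assert degrees(padj)[1] == degrees(adj)[1]
        assert clustering(padj)[1] == pytest.approx(clustering(adj)[1], abs=1e-14)
        assert global_efficiency(padj) == pytest.approx(
            global_efficiency(adj), abs=1e-14
        )
        if adj.n_edges:
            assert characteristic_path_length(padj).L == pytest.approx(
                characteristic_path_length(adj).L, abs=1e-14
            )


class TestRandomReferenceAndSigma:
    def test_complete_graph_singleton_ensemble(self):
        adj = make_canonical_graph("complete", 12)
        cc_r, l_r = random_reference(adj, n_realizations=5, seed=0)
        assert cc_r == 1.0
        assert l_r == 1.0
        sw = small_world_index(adj, n_realizations=5, seed=0)
        assert sw.sigma == 1.0
        assert sw.gamma == 1.0 and sw.lam == 1.0

    def test_ring_lattice_clustering_dominates_random(self):
        adj = make_canonical_graph("ring_lattice", 68, k=6)
        cc_real = clustering(adj)[1]
        cc_r, _ = random_reference(adj, n_realizations=10, seed=1)
        assert cc_real / cc_r > 2.0

    def test_zero_realizations_rejected(self):
        adj = make_canonical_graph("complete", 5)
        with pytest.raises(ValueError):
            random_reference(adj, n_realizations=0, seed=0)

    def test_reference_seed_reproducible(self):
        adj = make_canonical_graph("watts_strogatz", 40, seed=3, k=4, p=0.1)
        assert random_reference(adj, 8, seed=5) == random_reference(adj, 8, seed=5)


@pytest.fixture(scope="module")
def weights():
    rng = np.random.default_rng(77)
    w = rng.uniform(0, 0.6, (20, 20))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestMetricsTableAndMonotonicity:
    def test_compute_metrics_bundles_everything(self, weights):
        m = compute_metrics(weights, 0.2)
        assert m.average_degree == pytest.approx(m.degree.mean())
        np.testing.assert_allclose(m.strength, node_strength(weights))
        assert 0 <= m.efficiency <= 1
        assert m.n_connected_nodes <= 20

    def test_sweep_monotone_in_threshold(self, weights):
        table = metrics_table(weights, threshold_grid(), small_world=False)
        assert len(table) == 51
        for col in ["n_connected", "D", "E"]:
            assert np.all(np.diff(table[col].to_numpy()) <= 1e-12), col

    def test_small_world_columns_present(self, weights):
        table = metrics_table(weights, [0.1], n_realizations=5, seed=2)
        row = table.iloc[0]
        assert row["sigma"] == pytest.approx(row["gamma"] / row["lambda"])
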