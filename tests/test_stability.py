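"""Correlation graphs, Markov-stability partitions, exhaustive-search checks."""

import numpy as np
import pandas as pd
import pytest

from mesoproj import (
    CorrelationGraph,
    PartitionHierarchy,
    markov_stability_scan,
    merge_by_partition,
    partition_stability,
    region_correlation_graph,
)
from mesoproj.stability import GraphError, _stability_matrix


def set_partitions(n):
    """All set partitions of n items as restricted-growth label strings."""

    def rec(prefix, m):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(m + 1):
            yield from rec(prefix + [v], max(m, v + 1))

    yield from rec([], 0)


def brute_force_best(W, t):
    M = _stability_matrix(W, t)
    best = -np.inf
    for p in set_partitions(len(W)):
        lab = np.asarray(p)
        score = M[lab[:, None] == lab[None, :]].sum()
        if score > best:
            best = score
    return best


def random_graph(rng, n):
    W = np.round(rng.random((n, n)), 2)
    W = np.triu(W, 1)
    W = W + W.T
    W[W < 0.4] = 0.0
    for i in range(n):  # keep every node connected so brute force is comparable
        if W[i].sum() == 0:
            j = (i + 1) % n
            W[i, j] = W[j, i] = 0.5
    return W


class TestCorrelationGraph:
    def test_identical_columns_edge_weight_one(self):
        rng = np.random.default_rng(0)
        col = rng.random(6)
        df = pd.DataFrame({"A": col, "B": col, "C": rng.random(6)})
        g = region_correlation_graph(df)
        i, j = g.nodes.index("A"), g.nodes.index("B")
        assert g.weights[i, j] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair_zeroed(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"A": col, "B": -col + 5.0, "C": [1.0, 3.0, 2.0, 5.0]})
        g = region_correlation_graph(df)
        i, j = g.nodes.index("A"), g.nodes.index("B")
        assert g.weights[i, j] == 0.0

    def test_hand_computed_pearson_with_negative_entry(self):
        rng = np.random.default_rng(1)
        X = rng.random((5, 4))
        X[:, 3] = -2.0 * X[:, 0] + rng.random(5) * 0.01  # strongly negative vs col 0
        df = pd.DataFrame(X, columns=list("ABCD"))
        g = region_correlation_graph(df)
        C = np.corrcoef(X, rowvar=False)
        for a in range(4):
            for b in range(a + 1, 4):
                expected = max(C[a, b], 0.0)
                assert g.weights[a, b] == pytest.approx(expected, abs=1e-12)
        assert g.weights[0, 3] == 0.0  # the negative correlation was clipped

    def test_zero_variance_column_is_error(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        with pytest.raises(GraphError, match="B"):
            region_correlation_graph(df)

    def test_graph_invariants_enforced(self):
        with pytest.raises(GraphError, match="symmetric"):
            CorrelationGraph(("a", "b"), np.array([[0.0, 0.5], [0.2, 0.0]]))
        with pytest.raises(GraphError, match="diagonal"):
            CorrelationGraph(("a", "b"), np.array([[0.1, 0.5], [0.5, 0.0]]))


class TestStabilityScore:
    def test_whole_graph_partition_scores_zero(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 9):
            W = random_graph(rng, n)
            g = CorrelationGraph(tuple(f"n{i}" for i in range(n)), W)
            for t in (0.1, 1.0, 10.0):
                labels = {f"n{i}": 0 for i in range(n)}
                assert abs(partition_stability(g, t, labels)) <= 1e-10

    def test_tiny_time_prefers_singletons(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            W[i, j] = W[j, i] = 1.0
        g = CorrelationGraph(tuple("abcdef"), W)
        h = markov_stability_scan(g, times=[1e-4], n_restarts=5, seed=0)
        assert h[0].n_clusters == 6

    def test_two_disconnected_cliques_recovered_at_large_time(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            W[i, j] = W[j, i] = 1.0
        g = CorrelationGraph(tuple("abcdef"), W)
        h = markov_stability_scan(g, times=[10.0], n_restarts=10, seed=0)
        part = h[0]
        assert part.n_clusters == 2
        assert part.labels["a"] == part.labels["b"] == part.labels["c"]
        assert part.labels["d"] == part.labels["e"] == part.labels["f"]
        lab = np.array([0, 0, 0, 1, 1, 1])
        same = lab[:, None] == lab[None, :]
        expected = _stability_matrix(W, 10.0)[same].sum()
        assert part.stability == pytest.approx(expected, abs=1e-12)
        # hand computation of the t→∞ limit: within-clique M_ij → 1/18 − 1/36
        # = 1/36, so the two-block score approaches 2 · 9 · 1/36 = 1/2
        limit = _stability_matrix(W, 1e6)[same].sum()
        assert limit == pytest.approx(0.5, abs=1e-6)
        assert brute_force_best(W, 10.0) == pytest.approx(part.stability, abs=1e-10)

    def test_scan_matches_exhaustive_search_on_random_suite(self):
        """Louvain scan equals brute-force maximization over all partitions
        for a 20-graph suite of 5–7 node graphs at three Markov times."""
        rng = np.random.default_rng(42)
        for gi in range(20):
            n = int(rng.integers(5, 8))
            W = random_graph(rng, n)
            g = CorrelationGraph(tuple(f"n{i}" for i in range(n)), W)
            h = markov_stability_scan(g, times=[0.5, 1.0, 5.0], n_restarts=20, seed=gi)
            for scale, t in zip(h, (0.5, 1.0, 5.0)):
                assert scale.stability == pytest.approx(
                    brute_force_best(W, t), abs=1e-10
                ), f"graph {gi}, t={t}"

    def test_bell_number_sanity(self):
        assert sum(1 for _ in set_partitions(7)) == 877

    def test_isolated_nodes_stay_singletons(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.8
        g = CorrelationGraph(("a", "b", "iso1", "iso2"), W)
        h = markov_stability_scan(g, times=[0.5, 5.0], n_restarts=5, seed=1)
        for scale in h:
            assert scale.labels["iso1"] != scale.labels["iso2"]
            assert scale.labels["iso1"] not in (scale.labels["a"], scale.labels["b"])

    def test_scan_deterministic(self):
        rng = np.random.default_rng(3)
        W = random_graph(rng, 7)
        g = CorrelationGraph(tuple(f"n{i}" for i in range(7)), W)
        h1 = markov_stability_scan(g, times=[0.5, 2.0], n_restarts=10, seed=7)
        h2 = markov_stability_scan(g, times=[0.5, 2.0], n_restarts=10, seed=7)
        assert h1.to_json() == h2.to_json()

    def test_hierarchy_json_round_trip(self):
        rng = np.random.default_rng(4)
        W = random_graph(rng, 5)
        g = CorrelationGraph(tuple(f"n{i}" for i in range(5)), W)
        h = markov_stability_scan(g, times=[1.0], n_restarts=5, seed=0)
        assert PartitionHierarchy.from_json(h.to_json()) == h


class TestMerge:
    def test_singleton_partition_is_identity(self):
        df = pd.DataFrame(np.random.default_rng(5).random((3, 4)), columns=list("ABCD"))
        out = merge_by_partition(df, {"A": 0, "B": 1, "C": 2, "D": 3})
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy(), atol=0)

    def test_single_cluster_gives_row_sums(self):
        df = pd.DataFrame(np.random.default_rng(6).random((3, 4)), columns=list("ABCD"))
        out = merge_by_partition(df, dict.fromkeys("ABCD", 0))
        np.testing.assert_allclose(out.to_numpy()[:, 0], df.sum(axis=1), atol=1e-12)

    def test_hand_computed_two_cluster_merge(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]], columns=list("ABCD"))
        out = merge_by_partition(df, {"A": 0, "B": 0, "C": 1, "D": 1})
        np.testing.assert_array_equal(out.to_numpy(), [[3.0, 7.0], [11.0, 15.0]])

    def test_total_mass_conserved(self):
        df = pd.DataFrame(np.random.default_rng(7).random((4, 6)),
                          columns=[f"R{i}" for i in range(6)])
        labels = {f"R{i}": i % 2 for i in range(6)}
        out = merge_by_partition(df, labels)
        assert out.to_numpy().sum() == pytest.approx(df.to_numpy().sum(), abs=1e-12)

    def test_missing_label_is_error(self):
        df = pd.DataFrame(np.zeros((2, 2)), columns=["A", "B"])
        with pytest.raises(GraphError, match="B"):
            merge_by_partition(df, {"A": 0})
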