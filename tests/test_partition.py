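import itertools
import math

import numpy as np
import pytest

from netfrag import (
    Graph,
    Partition,
    clustering_coefficients,
    coarse_grain,
    detect_communities,
    modularity,
    partition_entropy,
    singleton_partition,
    weighted_clustering,
)
from netfrag.partition import load_partition, write_partition

from conftest import random_connected_graph


def exhaustive_best_bipartition(g):
    """Oracle: modularity-maximizing bipartition by enumerating all 2^(n-1)."""
    best_q, best = -2.0, None
    nodes = list(range(g.n))
    for bits in itertools.product([0, 1], repeat=g.n - 1):
        labels = [0] + list(bits)
        if len(set(labels)) < 2:
            continue
        q = modularity(g, Partition.from_labels(labels))
        if q > best_q:
            best_q, best = q, labels
    return best


class TestDetectCommunities:
    @pytest.mark.parametrize(
        "method", ["infomap", "walktrap", "label_propagation", "fast_greedy", "louvain"]
    )
    def test_two_cliques_recovered(self, two_cliques, method):
        p = detect_communities(two_cliques, method, seed=1)
        oracle = exhaustive_best_bipartition(two_cliques)
        assert p.n_communities == 2
        # same grouping as the exhaustive modularity optimum (the cliques)
        groups = {frozenset(i for i, l in enumerate(p.labels) if l == c)
                  for c in range(2)}
        oracle_groups = {frozenset(i for i, l in enumerate(oracle) if l == c)
                         for c in range(2)}
        assert groups == oracle_groups

    def test_complete_graph_single_community(self):
        g = Graph.from_edges([(i, j) for i in range(5) for j in range(i + 1, 5)])
        p = detect_communities(g, "louvain", seed=0)
        assert p.n_communities == 1

    def test_stochastic_methods_reproducible(self, two_cliques):
        a = detect_communities(two_cliques, "infomap", seed=5)
        b = detect_communities(two_cliques, "infomap", seed=5)
        assert a.labels == b.labels

    def test_unknown_method_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            detect_communities(two_cliques, "spectral")

    def test_simulated_annealing_unavailable(self, two_cliques):
        with pytest.raises(NotImplementedError):
            detect_communities(two_cliques, "simulated_annealing")

    def test_external_passthrough(self, tmp_path):
        g = Graph.from_edges([(0, 1), (1, 2), (2, 3)])
        path = tmp_path / "part.tsv"
        path.write_text("0\t0\n1\t0\n2\t1\n3\t1\n")
        p = detect_communities(g, "external", partition_path=path)
        assert p.labels == (0, 0, 1, 1)

    def test_external_unknown_node_rejected(self, tmp_path):
        g = Graph.from_edges([(0, 1)])
        path = tmp_path / "part.tsv"
        path.write_text("0\t0\n1\t0\n99\t1\n")
        with pytest.raises(ValueError, match="99"):
            load_partition(path, g)

    def test_partition_roundtrip(self, tmp_path, two_cliques):
        p = detect_communities(two_cliques, "louvain", seed=0)
        path = tmp_path / "p.tsv"
        write_partition(p, two_cliques, path)
        assert load_partition(path, two_cliques).labels == p.labels


class TestCoarseGrain:
    def test_singleton_partition_gives_adjacency(self, rng):
        g = random_connected_graph(20, rng)
        cg = coarse_grain(g, singleton_partition(g))
        a = np.zeros((g.n, g.n), dtype=int)
        for u, v in g.edges():
            a[u, v] = a[v, u] = 1
        assert np.array_equal(cg.a, a)

    def test_one_community_gives_zero_matrix(self, rng):
        g = random_connected_graph(10, rng)
        cg = coarse_grain(g, Partition.from_labels([0] * g.n))
        assert cg.a.shape == (1, 1) and cg.a.sum() == 0

    def test_fixture_weights(self, fixture8):
        g, p = fixture8
        cg = coarse_grain(g, p)
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 1] = expected[1, 0] = 2
        expected[1, 2] = expected[2, 1] = 1
        expected[2, 3] = expected[3, 2] = 3
        assert np.array_equal(cg.a, expected)
        assert cg.strengths.tolist() == [2, 3, 4, 3]
        assert cg.kappa.tolist() == [1, 2, 2, 1]

    def test_removal_deletes_incident_inter_links(self, fixture8):
        g, p = fixture8
        node5 = g.labels.index(5)
        cg = coarse_grain(g, p, removed={node5})
        # node 5 carried the C2-C3 link and one C3-C4 link
        assert cg.a[1, 2] == 0 and cg.a[2, 3] == 2

    def test_strength_plus_intra_accounts_all_edges(self, rng):
        g = random_connected_graph(24, rng)
        labels = [i % 3 for i in range(g.n)]
        p = Partition.from_labels(labels)
        cg = coarse_grain(g, p)
        intra = sum(1 for u, v in g.edges() if labels[u] == labels[v])
        assert cg.strengths.sum() // 2 + intra == g.m


class TestPartitionEntropy:
    def test_equipartition_maximal(self):
        p = Partition.from_labels([i // 25 for i in range(100)])
        h, h_norm = partition_entropy(p)
        assert h == pytest.approx(math.log(4))
        assert h_norm == pytest.approx(1.0)

    def test_single_community_zero(self):
        h, h_norm = partition_entropy(Partition.from_labels([0] * 10))
        assert h == 0.0 and h_norm == 1.0

    def test_skewed_sizes(self):
        labels = [0] * 99 + [1]
        h, _ = partition_entropy(Partition.from_labels(labels))
        assert h == pytest.approx(-0.99 * math.log(0.99) - 0.01 * math.log(0.01))

    def test_normalized_in_unit_interval_and_tight_iff_equal(self, rng):
        for _ in range(10):
            sizes = rng.integers(1, 20, size=int(rng.integers(2, 6)))
            labels = [c for c, s in enumerate(sizes) for _ in range(s)]
            h, h_norm = partition_entropy(Partition.from_labels(labels))
            assert 0.0 <= h_norm <= 1.0 + 1e-12
            if h_norm == pytest.approx(1.0):
                assert len(set(sizes.tolist())) == 1


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficients(Graph.from_edges([(0, 1), (1, 2), (2, 0)])) == 1.0

    def test_star(self):
        assert clustering_coefficients(Graph.from_edges([(0, i) for i in range(1, 5)])) == 0.0

    def test_k4_minus_edge(self):
        # degree-3 nodes: 2 triangles / C(3,2) = 2/3; degree-2 nodes: 1/1
        g = Graph.from_edges([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        assert clustering_coefficients(g) == pytest.approx((2 / 3 + 2 / 3 + 1 + 1) / 4)

    def test_weighted_reduces_to_unweighted_on_unit_weights(self, rng):
        g = random_connected_graph(15, rng)
        cg = coarse_grain(g, singleton_partition(g))
        assert weighted_clustering(cg) == pytest.approx(clustering_coefficients(g))

    def test_weighted_coarse_triangle(self):
        from netfrag.partition import CoarseGraph

        a = np.array([[0, 2, 1], [2, 0, 1], [1, 1, 0]])
        assert weighted_clustering(CoarseGraph(a)) == pytest.approx(1.0)

    def test_weighted_coarse_star_is_zero(self):
        from netfrag.partition import CoarseGraph

        a = np.zeros((4, 4), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        assert weighted_clustering(CoarseGraph(a)) == 0.0


class TestModularity:
    def test_single_community_zero(self, rng):
        g = random_connected_graph(12, rng)
        assert modularity(g, Partition.from_labels([0] * g.n)) == pytest.approx(0.0)

    def test_two_cliques_value(self, two_cliques):
        p = Partition.from_labels([0] * 5 + [1] * 5)
        assert modularity(two_cliques, p) == pytest.approx(20 / 21 - 0.5)

    def test_singleton_partition_value(self, rng):
        g = random_connected_graph(12, rng)
        expected = -sum((g.degree(i) / (2 * g.m)) ** 2 for i in range(g.n))
        assert modularity(g, singleton_partition(g)) == pytest.approx(expected)
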