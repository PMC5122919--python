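import networkx as nx
import numpy as np
import pytest

from netfrag import Graph, Partition, preprocess


@pytest.fixture
def fixture8():
    """8-node, 4-community worked example.

    Communities {1,2},{3,4},{5,6},{7,8}; intra edges 1-2,3-4,5-6,7-8; inter
    edges 2-3,1-3,4-5,5-7,6-7,6-8. Coarse weights: A~_12=2, A~_23=1, A~_34=3.
    """
    edges = [(1, 2), (3, 4), (5, 6), (7, 8),
             (2, 3), (1, 3), (4, 5), (5, 7), (6, 7), (6, 8)]
    g = Graph.from_edges(edges)
    p = Partition.from_labels([0, 0, 1, 1, 2, 2, 3, 3])
    return g, p


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by a single bridge edge (0-4 and 5-9)."""
    gnx = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    gnx.add_edge(4, 5)
    return Graph.from_networkx(gnx)


def random_connected_graph(n, rng, p=None):
    """Connected LCC of a sparse G(n, p) graph."""
    if p is None:
        p = 3.0 / n
    gnx = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
    return preprocess(Graph.from_networkx(gnx))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
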