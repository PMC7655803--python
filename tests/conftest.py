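import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connected_graph(rng, n_min=3, n_max=40, p=None):
    """A random connected graph for oracle comparisons (rejection draw)."""
    n = int(rng.integers(n_min, n_max + 1))
    if p is None:
        p = min(1.0, 2.5 / n + 0.05)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


@pytest.fixture
def paw():
    """Triangle with a pendant node."""
    return nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by a single link: the classic 2-community graph."""
    return nx.Graph(
        [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3)]
    )
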