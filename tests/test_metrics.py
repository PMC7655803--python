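"""Topology metric battery against hand calculations and brute-force oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from mitotopo.errors import InvalidParameterError
from mitotopo import metrics as M

from conftest import random_connected_graph


def _fw_stats(g):
    """All-pairs oracle via Floyd–Warshall on the dense adjacency."""
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes()), weight=None)
    d = floyd_warshall(a, unweighted=True)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    return d[off].mean(), int(d[off].max()), (1.0 / d[off]).mean()


class TestPairwiseMetrics:
    def test_path4_hand_enumeration(self):
        p4 = nx.path_graph(4)
        aspl, diam, eff = M.shortest_path_stats(p4)
        assert aspl == pytest.approx(10 / 6)
        assert diam == 3
        assert eff == pytest.approx((3 * 1 + 2 * 0.5 + 1 / 3) / 6)
        assert M.link_density(p4) == pytest.approx(0.5)
        assert M.max_degree(p4) == 2

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_complete_graph(self, n):
        k = nx.complete_graph(n)
        aspl, diam, eff = M.shortest_path_stats(k)
        assert (aspl, diam, eff) == (1.0, 1, 1.0)
        assert M.link_density(k) == 1.0
        assert M.max_degree(k) == n - 1

    def test_distance_metrics_match_floyd_warshall(self, rng):
        for _ in range(200):
            g = random_connected_graph(rng)
            aspl, diam, eff = M.shortest_path_stats(g)
            o_aspl, o_diam, o_eff = _fw_stats(g)
            assert aspl == pytest.approx(o_aspl)
            assert diam == o_diam
            assert eff == pytest.approx(o_eff)

    def test_disconnected_input_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(InvalidParameterError):
            M.shortest_path_stats(g)

    def test_efficiency_aspl_inequality_and_edge_monotonicity(self, rng):
        for _ in range(50):
            g = random_connected_graph(rng, n_max=20)
            aspl, diam, eff = M.shortest_path_stats(g)
            assert eff >= 1.0 / aspl - 1e-12  # harmonic-arithmetic
            assert diam >= aspl - 1e-12
            non_edges = list(nx.non_edges(g))
            if non_edges:
                u, v = non_edges[int(rng.integers(len(non_edges)))]
                g2 = g.copy()
                g2.add_edge(u, v)
                aspl2, diam2, _ = M.shortest_path_stats(g2)
                assert aspl2 <= aspl + 1e-12
                assert diam2 <= diam


class TestDegreeMetrics:
    def test_normalized_degree_values(self):
        g = nx.star_graph(9)  # hub degree 9 over N=10... hub k*=0.9
        ks = M.normalized_degree(g)
        assert ks[0] == pytest.approx(0.9)
        assert all(k == pytest.approx(0.1) for k in ks[1:])

    def test_handshake_identity(self, rng):
        for _ in range(30):
            g = random_connected_graph(rng, n_max=25)
            total = sum(M.normalized_degree(g))
            assert total == pytest.approx(
                2 * g.number_of_edges() / g.number_of_nodes()
            )

    def test_link_density_identity(self, rng):
        for _ in range(100):
            g = random_connected_graph(rng, n_max=30)
            n, l = g.number_of_nodes(), g.number_of_edges()
            assert M.link_density(g) == pytest.approx(2 * l / (n * (n - 1)))
            assert M.max_degree(g) == max(d for _, d in g.degree())

    def test_single_node_undefined(self):
        g = nx.Graph()
        g.add_node(0)
        assert M.link_density(g) is None
        assert M.max_degree(g) is None


def _modularity_exhaustive(g):
    """Best Newman–Girvan Q over all partitions (Bell-number search)."""
    nodes = sorted(g.nodes())

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    return max(
        nx.community.modularity(g, [set(b) for b in part])
        for part in partitions(nodes)
    )


class TestModularity:
    def test_two_triangles_bridge(self, two_triangles_bridge):
        parts, q = M.modularity_louvain(two_triangles_bridge, seed=0)
        assert q == pytest.approx(5 / 14)
        assert len(parts) == 2
        assert q == pytest.approx(_modularity_exhaustive(two_triangles_bridge))

    def test_louvain_matches_exhaustive_on_small_graphs(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_min=4, n_max=6)
            _, q = M.modularity_louvain(g, seed=0)
            assert q == pytest.approx(_modularity_exhaustive(g), abs=1e-9)

    def test_complete_graph_single_community(self):
        _, q = M.modularity_louvain(nx.complete_graph(6), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        g = random_connected_graph(rng, n_min=15, n_max=15)
        assert (
            M.modularity_louvain(g, seed=3)[1]
            == M.modularity_louvain(g, seed=3)[1]
        )


class TestAssortativity:
    def test_star_is_minus_one(self):
        assert M.assortativity(nx.star_graph(3)) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert M.assortativity(nx.cycle_graph(5)) is None
        assert M.assortativity(nx.complete_graph(4)) is None

    def test_matches_networkx_on_random_graphs(self, rng):
        checked = 0
        while checked < 25:
            g = random_connected_graph(rng, n_max=25)
            r = M.assortativity(g)
            if r is None:
                continue
            assert r == pytest.approx(
                nx.degree_assortativity_coefficient(g), abs=1e-8
            )
            checked += 1


class TestTransitivity:
    @pytest.mark.parametrize(
        "g,expected",
        [
            (nx.complete_graph(3), 1.0),
            (nx.star_graph(3), 0.0),
            (nx.complete_graph(4), 1.0),
        ],
    )
    def test_known_graphs(self, g, expected):
        assert M.transitivity(g) == expected

    def test_paw(self, paw):
        assert M.transitivity(paw) == pytest.approx(0.6)

    def test_matches_brute_force_triples(self, rng):
        for _ in range(30):
            g = random_connected_graph(rng, n_max=25)
            tri = 0
            triples = 0
            adj = {v: set(g.neighbors(v)) for v in g}
            for a, b, c in itertools.combinations(sorted(g), 3):
                e = (b in adj[a]) + (c in adj[a]) + (c in adj[b])
                if e == 3:
                    tri += 1
                    triples += 3
                elif e == 2:
                    triples += 1
            expected = 3 * tri / triples if triples else 0.0
            assert M.transitivity(g) == pytest.approx(expected)


class TestInformationContent:
    def test_complete_graph_is_zero(self):
        assert M.information_content(nx.complete_graph(12)) == 0.0

    def test_twin_nodes_merge_for_free(self):
        # every merge in a star pairs twin leaves (identical rows): 0 bits
        assert M.information_content(nx.path_graph(3)) == 0.0
        assert M.information_content(nx.star_graph(5)) == 0.0

    def test_er_graphs_more_irregular_than_complete(self, rng):
        vals = []
        for _ in range(20):
            g = random_connected_graph(rng, n_min=12, n_max=12, p=0.5)
            vals.append(M.information_content(g))
        assert np.mean(vals) > M.information_content(nx.complete_graph(12))


class TestComponentsAndPooling:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (10, 11), (11, 12), (12, 10)])
        comps = M.extract_components(g)
        assert [c.number_of_nodes() for c in comps] == [3, 3]
        assert min(comps[0].nodes()) == 0  # tie broken by smallest node id

    def test_empty_network(self):
        assert M.extract_components(nx.Graph()) == []

    def test_matches_bfs_oracle(self, rng):
        g = nx.gnp_random_graph(50, 0.03, seed=7)
        comps = M.extract_components(g)
        flood = list(nx.connected_components(g))
        assert sorted(map(len, comps), reverse=True) == sorted(
            map(len, flood), reverse=True
        )
        assert {frozenset(c.nodes()) for c in comps} == {
            frozenset(c) for c in flood
        }

    def test_size_filter_inclusive(self):
        values = [(10, 1.0), (24, 2.0), (30, 3.0)]
        assert M.global_metric_distribution(values, (24, 28)) == [2.0]
        assert M.global_metric_distribution(values) == [1.0, 2.0, 3.0]

    def test_inverted_filter_rejected(self):
        with pytest.raises(InvalidParameterError):
            M.global_metric_distribution([(5, 1.0)], (10, 2))

    def test_undefined_values_dropped(self):
        vals = [(5, None), (6, float("nan")), (7, 1.5)]
        assert M.global_metric_distribution(vals) == [1.5]
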