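"""Connected G(n, l) null ensembles: exactness, uniformity, Z-scores."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mitotopo.errors import InvalidParameterError
from mitotopo.nullmodel import (
    NullCache,
    build_null,
    default_bin_edges,
    random_connected_graph,
    zscore,
    zscore_probability,
)

from conftest import random_connected_graph as random_component


def _enumerate_connected(n, l):
    """All connected labeled graphs with n nodes and l edges."""
    pairs = list(itertools.combinations(range(n), 2))
    out = []
    for combo in itertools.combinations(pairs, l):
        g = nx.Graph(combo)
        g.add_nodes_from(range(n))
        if nx.is_connected(g):
            out.append(frozenset(combo))
    return out


class TestSampler:
    def test_parameter_validation(self, rng):
        with pytest.raises(InvalidParameterError):
            random_connected_graph(1, 0, rng)
        with pytest.raises(InvalidParameterError):
            random_connected_graph(4, 2, rng)  # below n-1
        with pytest.raises(InvalidParameterError):
            random_connected_graph(4, 7, rng)  # above n(n-1)/2

    def test_exact_counts_and_connectivity(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 15))
            lmax = n * (n - 1) // 2
            l = int(rng.integers(n - 1, lmax + 1))
            g = random_connected_graph(n, l, rng)
            assert g.number_of_nodes() == n
            assert g.number_of_edges() == l
            assert nx.is_connected(g)

    def test_unique_graph_cases(self, rng):
        g = random_connected_graph(5, 10, rng)
        assert nx.is_isomorphic(g, nx.complete_graph(5))

    @pytest.mark.parametrize("n,l,draws", [(3, 2, 3000), (4, 3, 8000)])
    def test_uniform_over_connected_graphs(self, n, l, draws, rng):
        support = _enumerate_connected(n, l)
        if (n, l) == (4, 3):
            assert len(support) == 16  # Cayley: 4^2 labeled trees
        counts = dict.fromkeys(support, 0)
        for _ in range(draws):
            g = random_connected_graph(n, l, rng)
            counts[frozenset(tuple(sorted(e)) for e in g.edges())] += 1
        p = 1 / len(support)
        se = np.sqrt(p * (1 - p) * draws)
        for c in counts.values():
            assert abs(c - draws * p) < 4 * se


class TestEnsembles:
    def test_unique_graph_gives_zero_sd(self):
        ens = build_null(nx.complete_graph(4), n_random=30, rng=0)
        assert ens.sd("aspl") == 0.0
        assert ens.sd("transitivity") == 0.0

    def test_members_exact(self, rng):
        g = random_component(rng, n_min=5, n_max=12)
        ens = build_null(g, n_random=40, rng=rng, keep_graphs=True)
        for member in ens.graphs:
            assert member.number_of_nodes() == ens.n
            assert member.number_of_edges() == ens.l
            assert nx.is_connected(member)

    def test_mean_stability_under_doubling(self, rng):
        g = nx.gnp_random_graph(10, 0.35, seed=3)
        assert nx.is_connected(g)
        e1 = build_null(g, n_random=100, rng=1)
        e2 = build_null(g, n_random=200, rng=2)
        sd = e1.sd("aspl")
        assert abs(e1.mean("aspl") - e2.mean("aspl")) < 3 * sd / np.sqrt(100)

    def test_cache_is_order_independent(self):
        c1 = NullCache(n_random=20, seed=5)
        c2 = NullCache(n_random=20, seed=5)
        a = c1.get(6, 7)
        _ = c2.get(9, 10)
        b = c2.get(6, 7)
        for key in a.summaries:
            np.testing.assert_array_equal(a.summaries[key], b.summaries[key])


class TestZScores:
    def test_formula(self):
        ens = build_null((6, 7), n_random=30, rng=0)
        mu = ens.mean("aspl")
        sd = ens.sd("aspl")
        rec = zscore(mu + 2 * sd, ens, "aspl")
        assert rec.z == pytest.approx(2.0)
        assert zscore(mu, ens, "aspl").z == pytest.approx(0.0)

    def test_zero_sd_flagged(self):
        ens = build_null(nx.complete_graph(4), n_random=20, rng=0)
        rec = zscore(1.0, ens, "aspl")
        assert rec.undefined and rec.z is None

    def test_self_consistency(self, rng):
        # null members scored against their own ensemble: mean 0, SD 1
        means, sds = [], []
        for _ in range(25):
            g = random_component(rng, n_min=5, n_max=12)
            ens = build_null(
                g, n_random=60, rng=rng,
                metric_names=("aspl", "diameter", "efficiency",
                              "transitivity"),
                count_motifs=False,
            )
            vals = ens.values("aspl")
            sd = ens.sd("aspl")
            if sd == 0:
                continue
            z = (vals - ens.mean("aspl")) / sd
            means.append(z.mean())
            sds.append(z.std(ddof=1))
        assert abs(np.mean(means)) < 0.1
        assert 0.9 < np.mean(sds) < 1.1


class TestZHistogram:
    def test_direct_fraction(self):
        z = np.array([0.1] * 3 + [2.6] * 9)
        edges, probs = zscore_probability(z, np.array([0.0, 1.0, 3.0]))
        assert probs[0] == pytest.approx(3 / 12)

    def test_single_covering_bin(self):
        _, probs = zscore_probability(
            np.array([0.5, -1.0, 2.0]), np.array([-10.0, 10.0])
        )
        assert probs[0] == 1.0

    def test_default_bins_conserve_probability(self, rng):
        z = rng.normal(size=500) * 3
        _, probs = zscore_probability(z, default_bin_edges())
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(InvalidParameterError):
            zscore_probability(np.array([np.nan]))

    def test_unsorted_edges_rejected(self):
        with pytest.raises(InvalidParameterError):
            zscore_probability(np.array([1.0]), np.array([1.0, 0.0]))
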