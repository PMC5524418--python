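"""Scale-free graph generator: degree draws, wiring, serialization."""

import numpy as np
import pytest
from scipy import integrate, stats

from isrnet import (
    Topology,
    draw_degree_sequence,
    load_edge_list,
    network_stats,
    random_scale_free,
    save_edge_list,
    truncation_bounds,
    wire_network,
)
from isrnet.topology import sample_truncated_power_law


class TestTruncationBounds:
    def test_numeric_integration_oracle(self):
        # the solved k0 must reproduce <k> under direct numerical integration
        for N, gamma, k_mean in [(200, 3.0, 5.0), (200, 2.1, 5.0), (200, 3.0, 20.0)]:
            k0, k_max = truncation_bounds(N, gamma, k_mean)
            assert k_max == pytest.approx(np.sqrt(N * k_mean))
            num, _ = integrate.quad(lambda k: k * k ** -gamma, k0, k_max)
            den, _ = integrate.quad(lambda k: k ** -gamma, k0, k_max)
            assert num / den == pytest.approx(k_mean, rel=1e-8)

    def test_pij_cap(self):
        # with k_max = sqrt(N <k>), max p_ij = k_max^2/(N<k>) = 1
        k0, k_max = truncation_bounds(400, 3.0, 7.0)
        assert k_max**2 / (400 * 7.0) == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            truncation_bounds(200, 1.9, 5.0)
        with pytest.raises(ValueError):
            truncation_bounds(1, 3.0, 1.0)


class TestDegreeSequence:
    def test_deterministic_under_seed(self):
        d1 = draw_degree_sequence(100, 3.0, 5.0, np.random.Generator(np.random.Philox(7)))
        d2 = draw_degree_sequence(100, 3.0, 5.0, np.random.Generator(np.random.Philox(7)))
        assert np.array_equal(d1, d2)

    def test_bounds_and_even_sum(self, rng):
        for _ in range(20):
            d = draw_degree_sequence(200, 3.0, 5.0, rng)
            assert d.min() >= 1
            assert d.max() <= np.sqrt(200 * 5.0) + 1  # +1 from the parity fix
            assert d.sum() % 2 == 0

    def test_ensemble_mean_degree(self, rng):
        # 200 draws of N=200: the average sample mean must track <k>=5
        means = [draw_degree_sequence(200, 3.0, 5.0, rng).mean() for _ in range(200)]
        assert np.mean(means) == pytest.approx(5.0, rel=0.10)

    def test_continuous_sampler_matches_cdf(self, rng):
        # KS test of the pre-rounding samples against the analytic CDF
        N, gamma, k_mean = 200, 3.0, 5.0
        k0, k_max = truncation_bounds(N, gamma, k_mean)
        xs = sample_truncated_power_law(5000, k0, k_max, gamma, rng)
        a = 1.0 - gamma

        def cdf(k):
            return (k**a - k0**a) / (k_max**a - k0**a)

        res = stats.kstest(xs, cdf)
        assert res.pvalue > 0.01


class TestWiring:
    def test_two_node_chain(self, rng):
        topo = wire_network(np.array([1, 1]), rng)
        assert topo.n_edges == 1
        assert np.array_equal(topo.edge_array(), [[0, 1]])

    def test_degrees_match_exactly_and_graph_is_simple(self, rng):
        for _ in range(5):
            d = draw_degree_sequence(150, 3.0, 5.0, rng)
            topo = wire_network(d, rng, gamma=3.0, k_mean=5.0)
            assert np.array_equal(topo.degrees, d)
            edges = topo.edge_array()
            assert np.all(edges[:, 0] < edges[:, 1])  # no self-loops
            keys = edges[:, 0] * topo.N + edges[:, 1]
            assert np.unique(keys).size == keys.size  # no multi-edges

    def test_adjacency_symmetric(self, rng):
        topo = random_scale_free(100, 3.0, 5.0, rng)
        from scipy.sparse import csr_matrix
        adj = csr_matrix(
            (np.ones_like(topo.indices), topo.indices, topo.indptr),
            shape=(topo.N, topo.N),
        )
        assert (adj != adj.T).nnz == 0
        assert adj.diagonal().sum() == 0

    def test_infeasible_degree_sum_rejected(self, rng):
        with pytest.raises(ValueError):
            wire_network(np.array([1, 1, 1]), rng)  # odd stub count


class TestNetworkStats:
    def test_regular_ring_fixture(self):
        N = 10
        edges = np.array([[i, (i + 1) % N] for i in range(N)])
        topo = Topology.from_edges(N, edges)
        s = network_stats(topo)
        assert s["mean_degree"] == 2.0
        assert np.isnan(s["gamma_hat"])  # all degrees equal: undefined

    def test_ensemble_mean_degree_and_exponent(self, rng):
        stats_ = [network_stats(random_scale_free(100, 3.0, 5.0, rng))
                  for _ in range(30)]
        mean_deg = np.mean([s["mean_degree"] for s in stats_])
        assert mean_deg == pytest.approx(5.0, rel=0.10)
        gammas = np.array([s["gamma_hat"] for s in stats_])
        # power-law tail consistent with the generating exponent
        assert abs(np.nanmean(gammas) - 3.0) < 1.0


class TestSerialization:
    def test_edge_list_roundtrip(self, rng, tmp_path):
        topo = random_scale_free(80, 3.0, 4.0, rng)
        path = tmp_path / "net.edges"
        save_edge_list(topo, path)
        back = load_edge_list(path)
        assert back.N == topo.N
        assert np.array_equal(back.degrees, topo.degrees)
        assert np.array_equal(back.edge_array(), topo.edge_array())
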