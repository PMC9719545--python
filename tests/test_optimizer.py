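import numpy as np
import pytest

import dualcomm as dc
from dualcomm.optimizer import (SourceModel, sigma_D2, injection_covariance,
                                sample_injections, mean_square_flows,
                                dissipation, optimize_network, prune_network,
                                graph_fiedler_values, transition_scan)


@pytest.fixture(scope="module")
def tri():
    return dc.triangular_lattice(4, 10)


class TestSourceModel:
    def test_sigma_d2_closed_form(self):
        assert abs(sigma_D2(500.0, 2, 0.01) - 250000 / (4 * 1.02)) < 1e-9

    def test_large_alpha_concentrates(self, tri):
        m = SourceModel(2, -1.0, 0.1, 500.0, 1e9)
        assert m.sigma_D2 < 1e-4
        mean, cov = injection_covariance(m, tri.graph, tri.sources)
        # source covariance reduces to the sink-balancing term
        s0, s1 = tri.source_indices
        n_sinks = tri.graph.n_nodes - 2
        assert abs(cov[s0, s0] - n_sinks * 0.01 / 4) < 1e-4

    def test_invalid_configs_rejected(self):
        with pytest.raises(dc.GraphError):
            SourceModel(n_sources=1)
        with pytest.raises(dc.GraphError):
            SourceModel(alpha=0.0)

    def test_samples_balanced_exactly(self, tri):
        m = SourceModel(2, -1.0, 0.1, 500.0, 0.5)
        P = sample_injections(m, tri.graph, tri.sources,
                              np.random.default_rng(0), 100)
        assert np.abs(P.sum(axis=1)).max() < 1e-10

    def test_covariance_rows_sum_to_zero(self, tri):
        m = SourceModel(2, -1.0, 0.1, 500.0, 0.3)
        mean, cov = injection_covariance(m, tri.graph, tri.sources)
        assert abs(mean.sum()) < 1e-9
        assert np.abs(cov.sum(axis=1)).max() < 1e-9

    def test_moments_match_monte_carlo(self, tri):
        """Pooled analytic moments vs 20k samples, studentized."""
        m = SourceModel(2, -1.0, 0.1, 500.0, 0.1)
        mean, cov = injection_covariance(m, tri.graph, tri.sources)
        rng = np.random.default_rng(11)
        P = sample_injections(m, tri.graph, tri.sources, rng, 20000)
        X = P - P.mean(axis=0)
        src = list(tri.source_indices)
        snk = [i for i in range(tri.graph.n_nodes) if i not in src]
        pools = {
            "sink_var": [(i, i) for i in snk],
            "source_var": [(i, i) for i in src],
            "source_source": [(src[0], src[1])],
            "source_sink": [(src[0], j) for j in snk],
        }
        n = P.shape[0]
        for name, pairs in pools.items():
            prods = np.mean([X[:, i] * X[:, j] for i, j in pairs], axis=0)
            target = np.mean([cov[i, j] for i, j in pairs])
            se = prods.std() / np.sqrt(n)
            assert abs(prods.mean() - target) < 5 * se, name


class TestMeanSquareFlows:
    def test_zero_covariance_gives_squared_flows(self, tri):
        g = tri.graph
        P = np.zeros(g.n_nodes)
        P[0], P[-1] = 1.0, -1.0
        msf = mean_square_flows(g, P, np.zeros((g.n_nodes, g.n_nodes)))
        F = dc.solve_flow(g, P).flows
        assert np.abs(msf - F**2).max() < 1e-12

    def test_symmetric_double_path(self):
        edges = [(0, 1), (1, 3), (0, 2), (2, 3)]
        coords = {0: (0, 0), 1: (1, 1), 2: (1, -1), 3: (2, 0)}
        g = dc.PlaneGraph.from_edgelist(edges, coords)
        P = np.array([1.0, 0, 0, -1.0])
        msf = mean_square_flows(g, P, np.zeros((4, 4)))
        assert np.allclose(msf, 0.25)

    def test_matches_gaussian_monte_carlo(self, tri):
        g = tri.graph
        rng = np.random.default_rng(2)
        A = rng.normal(size=(g.n_nodes, 5))
        A -= A.mean(axis=0)          # balanced support
        cov = A @ A.T
        mean = np.zeros(g.n_nodes)
        msf = mean_square_flows(g, mean, cov)
        samples = rng.multivariate_normal(mean, cov, size=20000,
                                          method="eigh")
        I = dc.build_incidence(g)
        T = (g.weights[:, None] * I) @ dc.laplacian_pinv(g)
        F = samples @ T.T
        emp = (F**2).mean(axis=0)
        se = (F**2).std(axis=0) / np.sqrt(len(samples))
        assert np.all(np.abs(emp - msf) < 5 * np.maximum(se, 1e-12))


class TestOptimize:
    def test_constraint_and_monotone_descent(self, tri):
        m = SourceModel(2, -1.0, 0.1, 500.0, 1.0)
        mean, cov = injection_covariance(m, tri.graph, tri.sources)
        res = optimize_network(tri.graph, mean, cov, gamma=0.9, seed=0)
        assert abs(np.sum(res.weights**0.9) - 1.0) < 1e-9
        h = np.array(res.history)
        assert np.all(np.diff(h) <= 1e-9 * h[:-1])
        assert res.converged

    def test_kkt_stationarity(self, tri):
        m = SourceModel(2, -1.0, 0.1, 500.0, 1.0)
        mean, cov = injection_covariance(m, tri.graph, tri.sources)
        res = optimize_network(tri.graph, mean, cov, gamma=0.9, seed=1)
        g = tri.graph.with_weights(res.weights)
        msf = mean_square_flows(g, mean, cov)
        alive = res.weights > 1e-8 * res.weights.max()
        ratio = msf[alive] / res.weights[alive]**1.9
        assert (ratio.max() - ratio.min()) / ratio.max() < 0.01

    def test_single_source_no_fluctuation_gives_tree(self, tri):
        g = tri.graph
        mean = np.full(g.n_nodes, -1.0)
        mean[0] = g.n_nodes - 1.0
        res = optimize_network(g, mean, np.zeros((g.n_nodes, g.n_nodes)),
                               gamma=0.9, n_restarts=3, seed=0)
        pruned = prune_network(g, res.weights, [g.nodes[0]])
        assert pruned.n_edges - pruned.n_nodes + 1 == 0  # loopless

    def test_invalid_gamma(self, tri):
        with pytest.raises(dc.GraphError):
            optimize_network(tri.graph, np.zeros(tri.graph.n_nodes),
                             np.zeros((2, 2)), gamma=1.5)


class TestTransitionScan:
    def test_columns_and_sigma_formula(self, tri):
        df = transition_scan(tri, [1e3, 1e-1], n_restarts=1, seed=0,
                             max_iter=300)
        assert len(df) == 2
        for _, row in df.iterrows():
            assert abs(row.sigma_D2
                       - sigma_D2(500.0, 2, row.alpha)) < 1e-9
        assert df.sigma_D2.is_monotonic_increasing

    def test_fiedler_values_of_forest_are_inf(self):
        g = dc.PlaneGraph.from_edgelist(
            [(0, 1), (1, 2)], {0: (0, 0), 1: (1, 0), 2: (2, 0)})
        lam2, lam2s = graph_fiedler_values(g)
        assert lam2 > 0 and lam2s == np.inf
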