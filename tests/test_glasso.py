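"""Graphical lasso, EBIC selection, and the precision→partial transform."""

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.glasso import kkt_residual, lambda_grid
from symptomnet.simulate import sample_partial_correlations

from _oracles import glasso_bruteforce_3x3


def _random_correlation(rng, p, n=60):
    return np.corrcoef(rng.standard_normal((n, p)), rowvar=False)


class TestGlassoFit:
    def test_full_shrinkage_at_lambda_max(self):
        rng = np.random.default_rng(0)
        S = _random_correlation(rng, 5)
        lam_max = np.abs(S - np.eye(5)).max()
        K = sn.glasso_fit(S, lam_max * 1.0001).K
        assert np.count_nonzero(K - np.diag(np.diag(K))) == 0
        assert np.allclose(np.diag(K), 1.0 / np.diag(S))

    def test_identity_input_no_penalty(self):
        K = sn.glasso_fit(np.eye(4), 0.0).K
        assert np.allclose(K, np.eye(4), atol=1e-8)

    def test_kkt_residual_small(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            S = _random_correlation(rng, 6)
            lam = rng.uniform(0.02, 0.3)
            K = sn.glasso_fit(S, lam).K
            assert kkt_residual(S, K, lam) < 1e-5

    def test_matches_bruteforce_on_three_nodes(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            S = _random_correlation(rng, 3, n=40)
            lam = rng.uniform(0.05, 0.3)
            K = sn.glasso_fit(S, lam).K
            K_oracle = glasso_bruteforce_3x3(S, lam)
            assert np.max(np.abs(K - K_oracle)) < 1e-4

    def test_matches_sklearn_reference(self):
        # independent implementation of the same off-diagonal-penalized
        # program; sklearn's duality-gap stopping rule stalls around 1e-4
        # on some instances, hence the looser comparison than the oracle's
        import warnings as _warnings

        from sklearn.covariance import graphical_lasso
        from sklearn.exceptions import ConvergenceWarning

        rng = np.random.default_rng(3)
        for _ in range(5):
            S = _random_correlation(rng, 6)
            lam = rng.uniform(0.05, 0.25)
            K = sn.glasso_fit(S, lam).K
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", ConvergenceWarning)
                _, K_ref = graphical_lasso(S, alpha=lam, tol=1e-8, max_iter=2000)
            assert np.max(np.abs(K - K_ref)) < 1e-3

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            sn.glasso_fit(np.eye(3), -0.1)


class TestEbic:
    def test_three_node_case_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        S = _random_correlation(rng, 3)
        K = sn.glasso_fit(S, 0.05).K
        n, gamma = 120, 0.5
        sign, logdet = np.linalg.slogdet(K)
        E = np.count_nonzero(np.triu(K, 1))
        expected = -n * (logdet - np.sum(S * K)) + E * np.log(n) + 4 * E * gamma * np.log(3)
        assert sn.ebic(K, S, n, gamma) == pytest.approx(expected, rel=1e-12)

    def test_identity_case(self):
        # K = S = I: log det = 0, trace = p, zero edges
        p, n = 4, 50
        assert sn.ebic(np.eye(p), np.eye(p), n) == pytest.approx(n * p)

    def test_penalty_arithmetic_for_one_extra_edge(self):
        # same likelihood, one extra edge costs log(n) + 4*gamma*log(p)
        n, gamma, p = 200, 0.5, 4
        K0 = np.eye(p)
        K1 = np.eye(p)
        K1[0, 1] = K1[1, 0] = 1e-300  # negligible likelihood change, one edge
        delta = sn.ebic(K1, np.eye(p), n, gamma) - sn.ebic(K0, np.eye(p), n, gamma)
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(p), rel=1e-9)

    def test_selection_invariant_to_additive_constant(self):
        # only EBIC differences matter: shifting all scores preserves argmin
        rng = np.random.default_rng(5)
        S = _random_correlation(rng, 5, n=500)
        _, path = sn.select_network(S, n=500)
        shifted = path.ebic + 123.456
        assert np.argmin(shifted) == path.selected

    def test_non_pd_precision_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            sn.ebic(K, np.eye(2), 50)


class TestSelectNetwork:
    def test_identity_matrix_gives_empty_network(self):
        net, path = sn.select_network(np.eye(5) , n=100)
        assert len(net.edges()) == 0
        assert (path.edge_counts == 0).all()

    def test_three_node_chain_recovery(self, chain3):
        """Planted chain weights are recovered; the null pair stays at the
        sampling-noise scale (EBIC applies no post-hoc threshold, so an
        edge of order 1/sqrt(n) may be retained with a near-zero weight)."""
        x = sn.sample_latent(chain3, 100_000, seed=31)
        S = np.corrcoef(x, rowvar=False)
        net, _ = sn.select_network(S, n=100_000)
        edges = {(a, b) for a, b, _, _ in net.edges()}
        assert {("v0", "v1"), ("v1", "v2")} <= edges
        assert net.weights[0, 1] == pytest.approx(0.4, abs=0.02)
        assert net.weights[1, 2] == pytest.approx(0.3, abs=0.02)
        assert abs(net.weights[0, 2]) <= 0.01

    def test_edge_count_monotone_along_path(self, chain3):
        x = sn.sample_latent(chain3, 2_000, seed=32)
        S = np.corrcoef(x, rowvar=False)
        _, path = sn.select_network(S, n=2_000)
        assert np.all(np.diff(path.lambdas) < 0)  # strictly decreasing grid
        assert np.all(np.diff(path.edge_counts) >= 0)  # sparser at larger lambda

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            sn.select_network(np.eye(5), n=3)

    def test_lambda_grid_shape(self):
        rng = np.random.default_rng(6)
        S = _random_correlation(rng, 4)
        grid = lambda_grid(S, 100, 0.01)
        assert len(grid) == 100
        assert grid[0] == pytest.approx(np.abs(S - np.eye(4)).max())
        assert grid[-1] == pytest.approx(grid[0] * 0.01)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_empty_network(self):
        prec = sn.PrecisionMatrix(("a", "b"), np.diag([2.0, 3.0]), 0.1)
        net = sn.precision_to_partial(prec)
        assert np.array_equal(net.weights, np.zeros((2, 2)))

    def test_closed_form_two_by_two(self):
        prec = sn.PrecisionMatrix(("a", "b"), np.array([[2.0, -1.0], [-1.0, 2.0]]), 0.0)
        assert sn.precision_to_partial(prec).weights[0, 1] == pytest.approx(0.5)

    def test_sign_convention(self):
        prec = sn.PrecisionMatrix(("a", "b"), np.array([[1.0, 0.3], [0.3, 1.0]]), 0.0)
        assert sn.precision_to_partial(prec).weights[0, 1] == pytest.approx(-0.3)

    def test_zero_pattern_preserved(self, chain3):
        x = sn.sample_latent(chain3, 5_000, seed=33)
        S = np.corrcoef(x, rowvar=False)
        prec = sn.glasso_fit(S, 0.05)
        net = sn.precision_to_partial(prec)
        off = ~np.eye(3, dtype=bool)
        assert np.array_equal(net.weights[off] == 0, prec.K[off] == 0)

    def test_binary_incident_edges_unsigned(self):
        K = np.array([[1.0, -0.3, 0.0], [-0.3, 1.0, -0.2], [0.0, -0.2, 1.0]])
        prec = sn.PrecisionMatrix(("csi", "gender", "pcs"), K, 0.0)
        net = sn.precision_to_partial(prec, binary_labels=("gender",))
        assert net.sign_class[0, 1] == "unsigned-categorical"
        assert net.sign_class[1, 2] == "unsigned-categorical"
        assert net.weights[0, 1] > 0  # numeric sign retained

    def test_non_pd_rejected(self):
        prec = sn.PrecisionMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]), 0.0)
        with pytest.raises(ValueError, match="positive definite"):
            sn.precision_to_partial(prec)


class TestRecoveryConsistency:
    def test_planted_14_node_network_recovered(self, planted_network, continuous_cohort_20k):
        """Planting the full default network and re-estimating at n = 20,000
        recovers every edge within 0.03 and no spurious edge above 0.03."""
        model = sn.SymptomNetworkModel(continuous_cohort_20k, correlation="pearson")
        res = model.fit()
        est = res.network.weights
        truth = planted_network.partials
        mask = truth != 0
        assert np.max(np.abs(est[mask] - truth[mask])) <= 0.03
        assert np.max(np.abs(est[~mask])) <= 0.03

    def test_graphml_and_adjacency_export(self, tmp_path, chain3):
        import networkx as nx

        x = sn.sample_latent(chain3, 10_000, seed=34)
        S = np.corrcoef(x, rowvar=False)
        net, _ = sn.select_network(S, n=10_000)
        net.to_graphml(tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == len(net.edges())
        assert all(d["colour"] == "green" for _, _, d in g.edges(data=True))
        net.to_adjacency_csv(tmp_path / "adj.csv")
        assert (tmp_path / "adj.csv").read_text().startswith(",v0,v1,v2")
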