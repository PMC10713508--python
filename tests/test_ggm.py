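"""Graphical-lasso estimation, EBIC selection and network summaries."""

import numpy as np
import pytest

from shsnet.association import CorrelationMatrix
from shsnet.ggm import (
    EstimationConfig,
    ebic_score,
    estimate_network,
    glasso_fit,
    lambda_path,
    network_summary,
    penalised_objective,
    precision_to_partial,
)
from shsnet.studies import _brute_force_glasso


def _corr(values, method="pearson"):
    values = np.asarray(values, dtype=float)
    p = values.shape[0]
    return CorrelationMatrix(
        labels=[f"V{i+1}" for i in range(p)], values=values, method=method, n_effective=100
    )


S2 = np.array([[1.0, 0.5], [0.5, 1.0]])
S3 = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, -0.3], [0.2, -0.3, 1.0]])


class TestGlassoFit:
    def test_lambda_zero_is_inverse(self):
        theta = glasso_fit(S3, 0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(S3), atol=1e-6)

    def test_large_lambda_gives_diagonal(self):
        lam = np.abs(S3[~np.eye(3, dtype=bool)]).max()
        theta = glasso_fit(S3, lam + 0.01)
        off = theta[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_bivariate_soft_threshold(self):
        # p = 2, s = 0.5, lambda = 0.2: partial correlation (0.5-0.2)=0.3
        theta = glasso_fit(S2, 0.2, EstimationConfig(tol=1e-8, max_iter=1000))
        pc = precision_to_partial(theta)
        assert pc[0, 1] == pytest.approx(0.3, abs=1e-6)

    @pytest.mark.parametrize("S", [S2, S3], ids=["p2", "p3"])
    @pytest.mark.parametrize("lam", [0.0, 0.05, 0.2, 0.4])
    def test_matches_brute_force_optimiser(self, S, lam):
        theta = glasso_fit(S, lam, EstimationConfig(tol=1e-10, max_iter=2000))
        oracle = _brute_force_glasso(S, lam)
        assert np.abs(theta - oracle).max() < 1e-4
        # and the solver's objective is never worse than the oracle's
        assert penalised_objective(theta, S, lam) >= penalised_objective(
            oracle, S, lam
        ) - 1e-8

    def test_non_pd_input_directed_to_repair(self):
        bad = np.array([[1.0, 0.9, -0.3], [0.9, 1.0, 0.9], [-0.3, 0.9, 1.0]])
        with pytest.raises(ValueError, match="nearest_pd"):
            glasso_fit(bad, 0.1)


class TestLambdaPath:
    def test_path_construction(self):
        cfg = EstimationConfig(n_lambdas=100, lambda_min_ratio=0.01)
        path = lambda_path(S3, cfg)
        assert len(path) == 100
        assert path[0] == pytest.approx(0.4)  # max |off-diagonal|
        assert path[-1] == pytest.approx(0.4 * 0.01)
        assert np.all(np.diff(path) < 0)

    def test_diagonal_matrix_single_point_path(self):
        with pytest.warns(UserWarning, match="single-point"):
            path = lambda_path(np.eye(4))
        np.testing.assert_array_equal(path, [0.0])


class TestEbicScore:
    def test_hand_computed_value(self):
        # n=100, p=3, E=2, gamma=0.5, ll=-150 -> 300 + 2 ln 100 + 2*2 ln 3
        theta = np.array([[1.0, 0.2, 0.0], [0.2, 1.0, 0.1], [0.0, 0.1, 1.0]])
        n = 100
        sign, logdet = np.linalg.slogdet(theta)
        S = np.eye(3)
        ll = 0.5 * n * (logdet - np.trace(S @ theta))
        expected = -2 * ll + 2 * np.log(100) + 4 * 0.5 * 2 * np.log(3)
        assert ebic_score(theta, S, n, gamma=0.5) == pytest.approx(expected, rel=1e-12)
        # the stated arithmetic with ll = -150:
        assert 300 + 2 * np.log(100) + 2 * 2 * np.log(3) == pytest.approx(313.60, abs=0.01)

    def test_gamma_zero_reduces_to_bic(self):
        theta = np.array([[1.2, -0.3], [-0.3, 1.2]])
        bic = ebic_score(theta, S2, 50, gamma=0.0)
        sign, logdet = np.linalg.slogdet(theta)
        ll = 0.5 * 50 * (logdet - np.trace(S2 @ theta))
        assert bic == pytest.approx(-2 * ll + 1 * np.log(50), rel=1e-12)

    def test_extra_zero_weight_edge_cannot_improve(self):
        base = np.array([[1.1, 0.0], [0.0, 1.1]])
        with_edge = np.array([[1.1, 1e-6], [1e-6, 1.1]])
        assert ebic_score(with_edge, S2, 100) >= ebic_score(base, S2, 100)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            ebic_score(np.array([[1.0, 2.0], [2.0, 1.0]]), S2, 100)


class TestEstimateNetwork:
    def test_identity_correlation_empty_network(self):
        with pytest.warns(UserWarning):
            net = estimate_network(_corr(np.eye(5)), n=100)
        assert network_summary(net).edge_count == 0

    def test_bivariate_selection_matches_enumeration(self):
        # enumeration oracle: EBIC of the dense MLE vs the diagonal model
        n = 100
        dense = np.linalg.inv(S2)
        sparse = np.diag(1.0 / np.diag(S2))
        pick_edge = ebic_score(dense, S2, n) < ebic_score(sparse, S2, n)
        net = estimate_network(_corr(S2), n=n)
        has_edge = net.weights[0, 1] != 0
        assert has_edge == pick_edge

    def test_monotone_sparsity_along_path(self, small_cohort):
        from shsnet.association import correlation_matrix

        S = correlation_matrix(small_cohort, method="pearson")
        cfg = EstimationConfig(n_lambdas=20, lambda_min_ratio=0.05)
        counts = []
        for lam in lambda_path(S, cfg):
            theta = glasso_fit(S.values, float(lam), cfg)
            iu = np.triu_indices(8, 1)
            counts.append(int((np.abs(theta[iu]) > 1e-8).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_partial_correlations_at_lambda_zero_are_classical(self):
        theta = glasso_fit(S3, 0.0)
        pc = precision_to_partial(theta)
        inv = np.linalg.inv(S3)
        d = np.sqrt(np.diag(inv))
        expected = -inv / np.outer(d, d)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(pc, expected, atol=1e-10)

    def test_estimation_is_deterministic(self, small_cohort, fast_config):
        from shsnet.association import correlation_matrix

        S = correlation_matrix(small_cohort, method="pearson")
        a = estimate_network(S, n=300, config=fast_config)
        b = estimate_network(S, n=300, config=fast_config)
        assert np.array_equal(a.weights, b.weights)
        assert a.lambda_ == b.lambda_

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EstimationConfig(gamma=-0.1)
        with pytest.raises(ValueError):
            EstimationConfig(n_lambdas=1)
        with pytest.raises(ValueError):
            EstimationConfig(lambda_min_ratio=1.5)


class TestNetworkSummary:
    @pytest.mark.parametrize(
        "edges, density", [(58, 0.193), (43, 0.143)]
    )
    def test_published_density_arithmetic(self, edges, density):
        # place the requested number of edges on 25 nodes
        p = 25
        W = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        W[iu[0][:edges], iu[1][:edges]] = 0.05
        W = W + W.T
        from shsnet.ggm import PartialCorrelationNetwork

        net = PartialCorrelationNetwork(
            labels=[f"V{i}" for i in range(p)], weights=W, precision=np.eye(p),
            lambda_=0.1, ebic=0.0, n=100,
        )
        summ = network_summary(net)
        assert summ.possible_edges == 300
        assert summ.edge_count == edges
        assert round(summ.density, 3) == density

    def test_empty_network_flagged(self):
        from shsnet.ggm import PartialCorrelationNetwork

        net = PartialCorrelationNetwork(
            labels=["a", "b"], weights=np.zeros((2, 2)), precision=np.eye(2),
            lambda_=0.5, ebic=0.0, n=10,
        )
        summ = network_summary(net)
        assert summ.density == 0.0
        assert summ.mean_abs_nonzero_weight == 0.0
        assert summ.empty
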