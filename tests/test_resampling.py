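"""Bootstrap accuracy, difference tests, case-dropping stability, CS-coefficient."""

import numpy as np
import pytest

from shsnet.resampling import (
    BootstrapEnsemble,
    StabilityResult,
    bootstrap_edges,
    case_drop_stability,
    cs_coefficient,
    cs_from_quantile_curve,
    difference_tests,
)
from shsnet.ggm import EstimationConfig


@pytest.fixture(scope="module")
def small_ensemble(small_cohort_module, fast_config_module):
    ens, ci = bootstrap_edges(
        small_cohort_module, fast_config_module, B=120, seed=10, method="pearson"
    )
    return ens, ci


# module-scoped clones of the session fixtures so the ensemble is built once
@pytest.fixture(scope="module")
def small_cohort_module():
    from shsnet import cohort as cm

    truth = cm.make_truth_network(p=8, density=0.25, seed=42)
    return cm.generate_cohort(truth, cm.generic_preset(p=8, n=300), seed=7)


@pytest.fixture(scope="module")
def fast_config_module():
    return EstimationConfig(n_lambdas=12, lambda_min_ratio=0.1, tol=1e-3)


class TestBootstrapEdges:
    def test_cis_cover_point_estimates(self, small_ensemble):
        ens, ci = small_ensemble
        nonzero = ci[ci["estimate"] != 0]
        covered = (
            (nonzero["ci_lower"] <= nonzero["estimate"])
            & (nonzero["estimate"] <= nonzero["ci_upper"])
        ).mean()
        assert covered >= 0.9

    def test_fixed_seed_reproducible(self, small_cohort_module, fast_config_module):
        a, _ = bootstrap_edges(
            small_cohort_module, fast_config_module, B=20, seed=3, method="pearson"
        )
        b, _ = bootstrap_edges(
            small_cohort_module, fast_config_module, B=20, seed=3, method="pearson"
        )
        assert np.array_equal(a.weights, b.weights)

    def test_single_replicate_collapses_ci(self, small_cohort_module, fast_config_module):
        with pytest.warns(UserWarning, match="< 100"):
            _, ci = bootstrap_edges(
                small_cohort_module, fast_config_module, B=1, seed=5, method="pearson"
            )
        np.testing.assert_allclose(ci["ci_lower"], ci["ci_upper"])


class TestDifferenceTests:
    def test_edge_never_differs_from_itself(self, small_ensemble):
        ens, _ = small_ensemble
        mat = difference_tests(ens, target="edges")
        assert not np.diag(mat.to_numpy()).any()

    def test_identical_replicate_values_not_different(self):
        rng = np.random.default_rng(0)
        B, p = 150, 3
        W = np.zeros((B, p, p))
        w = rng.uniform(0.2, 0.4, B)
        W[:, 0, 1] = W[:, 1, 0] = w
        W[:, 0, 2] = W[:, 2, 0] = w  # same values in every replicate
        ens = BootstrapEnsemble(
            labels=["a", "b", "c"],
            weights=W,
            centralities={"strength": np.abs(W).sum(axis=2)},
            original_weights=W.mean(axis=0),
            original_centralities=None,
            seed=0,
            config=EstimationConfig(),
        )
        mat = difference_tests(ens, target="edges")
        assert not mat.loc["a--b", "a--c"]

    def test_separated_edges_flagged(self):
        rng = np.random.default_rng(1)
        B, p = 200, 3
        W = np.zeros((B, p, p))
        W[:, 0, 1] = W[:, 1, 0] = rng.normal(0.6, 0.02, B)
        W[:, 0, 2] = W[:, 2, 0] = rng.normal(0.0, 0.02, B)
        ens = BootstrapEnsemble(
            labels=["a", "b", "c"],
            weights=W,
            centralities={"strength": np.abs(W).sum(axis=2)},
            original_weights=W.mean(axis=0),
            original_centralities=None,
            seed=0,
            config=EstimationConfig(),
        )
        mat = difference_tests(ens, target="edges")
        assert mat.loc["a--b", "a--c"]


class TestCaseDropStability:
    def test_drop_curve_decreases_and_reproduces(
        self, small_cohort_module, fast_config_module
    ):
        res = case_drop_stability(
            small_cohort_module,
            fast_config_module,
            proportions=np.array([0.1, 0.3, 0.5, 0.7]),
            B_per_level=20,
            seed=8,
            method="pearson",
        )
        med = np.nanmedian(res.correlations["strength"], axis=1)
        assert med[-1] <= med[0] + 1e-12  # stochastically non-increasing
        res2 = case_drop_stability(
            small_cohort_module,
            fast_config_module,
            proportions=np.array([0.1, 0.3, 0.5, 0.7]),
            B_per_level=20,
            seed=8,
            method="pearson",
        )
        np.testing.assert_array_equal(
            res.correlations["strength"], res2.correlations["strength"]
        )

    def test_grid_truncated_for_small_samples(self, small_cohort_module, fast_config_module):
        from shsnet import cohort as cm

        tiny = cm.generate_cohort(
            cm.make_truth_network(p=8, density=0.25, seed=42),
            cm.generic_preset(p=8, n=40),
            seed=2,
        )
        with pytest.warns(UserWarning, match="truncating"):
            res = case_drop_stability(
                tiny, fast_config_module, B_per_level=5, seed=1, method="pearson"
            )
        assert np.floor((1 - res.proportions.max()) * 40) >= 20

    def test_empty_grid_rejected(self, small_cohort_module, fast_config_module):
        from shsnet import cohort as cm

        tiny = cm.generate_cohort(
            cm.make_truth_network(p=8, density=0.25, seed=42),
            cm.generic_preset(p=8, n=21),
            seed=2,
        )
        with pytest.raises(ValueError, match="empty"), pytest.warns(UserWarning):
            case_drop_stability(
                tiny, fast_config_module,
                proportions=np.array([0.5, 0.75]), B_per_level=5, seed=1,
                method="pearson",
            )


class TestCSCoefficient:
    def test_hand_computed_quantile_curve(self):
        curve = {0.1: 0.95, 0.2: 0.90, 0.3: 0.80, 0.4: 0.72, 0.5: 0.65}
        assert cs_from_quantile_curve(curve, corr_threshold=0.7) == 0.4

    def test_all_perfect_gives_max_grid(self):
        props = np.array([0.1, 0.3, 0.5, 0.75])
        res = StabilityResult(
            proportions=props,
            correlations={"strength": np.ones((4, 30))},
            B_per_level=30,
            seed=0,
            config=EstimationConfig(),
        )
        assert cs_coefficient(res)["strength"] == 0.75

    def test_all_below_threshold_gives_zero(self):
        props = np.array([0.1, 0.3])
        res = StabilityResult(
            proportions=props,
            correlations={"strength": np.full((2, 30), 0.5)},
            B_per_level=30,
            seed=0,
            config=EstimationConfig(),
        )
        assert cs_coefficient(res)["strength"] == 0.0

    def test_monotone_in_threshold_and_certainty(self):
        rng = np.random.default_rng(4)
        props = np.round(np.arange(0.05, 0.80, 0.05), 2)
        corr = np.clip(
            1 - props[:, None] * rng.uniform(0.5, 1.5, (len(props), 50)), -1, 1
        )
        res = StabilityResult(
            proportions=props, correlations={"strength": corr},
            B_per_level=50, seed=0, config=EstimationConfig(),
        )
        cs_loose = cs_coefficient(res, corr_threshold=0.5)["strength"]
        cs_tight = cs_coefficient(res, corr_threshold=0.9)["strength"]
        assert cs_tight <= cs_loose
        cs_50 = cs_coefficient(res, certainty=0.50)["strength"]
        cs_95 = cs_coefficient(res, certainty=0.95)["strength"]
        assert cs_95 <= cs_50
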