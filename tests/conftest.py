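import numpy as np
import pytest

from shsnet import cohort as cohort_mod
from shsnet.ggm import EstimationConfig
from shsnet.shsq import CANONICAL_ITEMS, LikertResponseMatrix


@pytest.fixture(scope="session")
def small_truth():
    """Sparse 8-node ground-truth network used across estimation tests."""
    return cohort_mod.make_truth_network(p=8, density=0.25, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """Ordinal cohort of 300 respondents generated from the small truth."""
    preset = cohort_mod.generic_preset(p=8, n=300)
    return cohort_mod.generate_cohort(small_truth, preset, seed=7)


@pytest.fixture(scope="session")
def fast_config():
    """Short-path estimation config keeping resampling tests quick."""
    return EstimationConfig(n_lambdas=12, lambda_min_ratio=0.1, tol=1e-3)


@pytest.fixture()
def canonical_matrix():
    """Deterministic valid 6-respondent canonical SHSQ-25 matrix."""
    rng = np.random.default_rng(0)
    ratings = rng.integers(0, 5, size=(6, 25)).astype(float)
    return LikertResponseMatrix(
        respondent_ids=[f"r{i}" for i in range(6)],
        items=list(CANONICAL_ITEMS),
        ratings=ratings,
    )
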