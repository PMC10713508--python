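"""Synthetic SHSQ-25-like cohorts from a known sparse partial-correlation truth.

The study cohort is not publicly deposited, so every downstream stage is
exercised on generated data: a sparse Gaussian graphical model supplies the
latent dependence structure, and each latent variable is discretised to the
0–4 ordinal scale with thresholds calibrated so the item marginal means match
published per-population targets (a Gaussian copula with ordinal margins).
Because the truth network is known, estimator output can be scored for edge
recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import optimize, stats

from .shsq import CANONICAL_ITEMS, LikertResponseMatrix

__all__ = [
    "GroundTruthNetwork",
    "CohortPreset",
    "make_truth_network",
    "generate_cohort",
    "recovery_metrics",
    "fit_item_thresholds",
    "load_item_targets",
]

_N_CATEGORIES = 5


@dataclass
class GroundTruthNetwork:
    """Known sparse partial-correlation structure behind a synthetic cohort."""

    partial_corr: np.ndarray  # symmetric, zero diagonal
    correlation: np.ndarray  # implied latent correlation matrix, PD, unit diag
    edge_density: float  # realised fraction of nonzero off-diagonal pairs
    seed: int | None = None

    @property
    def p(self) -> int:
        return self.partial_corr.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.count_nonzero(self.partial_corr[iu]))


@dataclass
class CohortPreset:
    """Per-item marginal targets (mean, SD on the 0–4 scale) and sample size."""

    name: str
    item_means: dict[str, float]
    item_sds: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        for item, mu in self.item_means.items():
            if not (0.0 <= mu <= 4.0):
                raise ValueError(f"target mean for {item} outside [0, 4]: {mu}")
            if self.item_sds[item] <= 0:
                raise ValueError(f"target SD for {item} must be positive")

    @property
    def items(self) -> list[str]:
        return list(self.item_means)


def load_item_targets() -> dict:
    """Published per-item mean/SD targets for the two study populations."""
    text = resources.files("shsnet.presets").joinpath("table2_item_targets.json").read_text()
    return json.loads(text)


def preset(name: str, n: int | None = None) -> CohortPreset:
    """Built-in presets: ``optimal_like`` and ``suboptimal_like``.

    Default sample sizes are the study's group sizes (106 and 111).
    """
    targets = load_item_targets()
    key = {"optimal_like": "optimal", "suboptimal_like": "suboptimal"}.get(name)
    if key is None:
        raise ValueError(f"unknown preset {name!r}; use 'optimal_like' or 'suboptimal_like'")
    means = {item: v[key][0] for item, v in targets["items"].items()}
    sds = {item: v[key][1] for item, v in targets["items"].items()}
    return CohortPreset(name=name, item_means=means, item_sds=sds, n=n or targets["n"][key])


def make_truth_network(
    p: int,
    density: float,
    weight_range: tuple[float, float] = (0.15, 0.35),
    seed: int | None = None,
    negative_fraction: float = 0.1,
) -> GroundTruthNetwork:
    """Random sparse partial-correlation truth with a positive-definite implied
    correlation matrix.

    Edge positions are sampled uniformly to hit the requested density;
    magnitudes are uniform on ``weight_range`` with a ``negative_fraction``
    share of negative signs (questionnaire networks are predominantly
    positive).  Positive definiteness is enforced by a uniform eigenvalue
    shift of the precision matrix followed by re-normalisation to unit
    partial variances, after which the stored partial correlations are
    recomputed so the truth object is self-consistent.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must be in [0, 1]")
    lo, hi = weight_range
    if not (-1 < lo <= hi < 1):
        raise ValueError(
            "infeasible weight_range: partial correlations must lie in (-1, 1); "
            "use smaller magnitudes"
        )
    rng = np.random.default_rng(seed)
    n_pairs = p * (p - 1) // 2
    n_edges = int(round(density * n_pairs))
    iu = np.triu_indices(p, 1)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    weights = rng.uniform(lo, hi, size=n_edges)
    signs = np.where(rng.random(n_edges) < negative_fraction, -1.0, 1.0)

    P = np.zeros((p, p))
    P[iu[0][chosen], iu[1][chosen]] = weights * signs
    P = P + P.T

    # precision with unit partial variances: theta_ij = -rho_ij (off-diag)
    theta = np.eye(p) - P
    w = np.linalg.eigvalsh(theta)
    if w[0] <= 1e-8:
        theta = theta + (abs(w[0]) + 0.05) * np.eye(p)
        d = np.sqrt(np.diag(theta))
        theta = theta / np.outer(d, d)
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)

    dprec = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(dprec, dprec)
    np.fill_diagonal(pc, 0.0)
    realised = np.count_nonzero(pc[iu]) / n_pairs if n_pairs else 0.0
    return GroundTruthNetwork(
        partial_corr=pc, correlation=corr, edge_density=float(realised), seed=seed
    )


def fit_item_thresholds(mean: float, sd: float) -> np.ndarray:
    """Standard-normal thresholds whose discretised variable hits a target mean.

    The item is modelled as a rounded (clipped) normal: categories
    k = 0..4 correspond to latent intervals split at 0.5, 1.5, 2.5, 3.5 on an
    N(μ, σ) scale with σ fixed at the target SD and μ found by 1-D root
    finding so that the category-probability-weighted mean equals the target.
    The resulting cumulative category probabilities are mapped back to
    standard-normal thresholds for copula discretisation.  Means are matched
    exactly (in distribution); SDs are emergent.
    """
    if not (0.0 < mean < 4.0):
        raise ValueError(
            f"target mean {mean} not attainable with finite thresholds; need 0 < mean < 4"
        )
    cuts = np.array([0.5, 1.5, 2.5, 3.5])

    def discretised_mean(mu: float) -> float:
        cdf = stats.norm.cdf((cuts - mu) / sd)
        probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
        return float(probs @ np.arange(_N_CATEGORIES))

    lo, hi = -20.0 * sd, 4.0 + 20.0 * sd
    mu = optimize.brentq(lambda m: discretised_mean(m) - mean, lo, hi, xtol=1e-12)
    cum = stats.norm.cdf((cuts - mu) / sd)
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(cum)


def generate_cohort(
    truth: GroundTruthNetwork,
    preset: CohortPreset,
    seed: int | None = None,
) -> LikertResponseMatrix:
    """Sample an ordinal cohort: latent MVN draw + per-item threshold cuts."""
    items = preset.items
    if truth.p != len(items):
        raise ValueError(f"truth dimension {truth.p} != preset item count {len(items)}")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        np.zeros(truth.p), truth.correlation, size=preset.n, method="cholesky"
    )
    ratings = np.empty_like(z)
    for j, item in enumerate(items):
        thr = fit_item_thresholds(preset.item_means[item], preset.item_sds[item])
        ratings[:, j] = np.searchsorted(thr, z[:, j])
    ids = [f"{preset.name}-{i:05d}" for i in range(preset.n)]
    if set(items) <= set(CANONICAL_ITEMS):
        domain_map = {i: i[:2] for i in items}
    else:
        domain_map = {i: "ALL" for i in items}
    return LikertResponseMatrix(
        respondent_ids=ids,
        items=items,
        ratings=ratings,
        domain_map=domain_map,
    )


def generic_preset(p: int, n: int, mean: float = 1.5, sd: float = 1.0) -> CohortPreset:
    """Homogeneous preset for simulation studies on ``p`` generic items."""
    items = [f"V{j+1}" for j in range(p)]
    return CohortPreset(
        name="custom",
        item_means={i: mean for i in items},
        item_sds={i: sd for i in items},
        n=n,
    )


def recovery_metrics(estimate, truth: GroundTruthNetwork) -> dict[str, float | None]:
    """Edge-recovery quality of an estimated network against the known truth.

    sensitivity — fraction of true edges recovered; specificity — fraction of
    true zero pairs estimated as zero; weight_correlation — Pearson
    correlation of estimated vs true weights over the true-edge pairs.
    """
    est_w = np.asarray(getattr(estimate, "weights", estimate))
    if est_w.shape != truth.partial_corr.shape:
        raise ValueError("estimate and truth dimensions differ")
    iu = np.triu_indices(truth.p, 1)
    true_edge = truth.partial_corr[iu] != 0
    est_edge = est_w[iu] != 0
    n_true = int(true_edge.sum())
    n_zero = int((~true_edge).sum())
    sens = float((est_edge & true_edge).sum() / n_true) if n_true else None
    spec = float((~est_edge & ~true_edge).sum() / n_zero) if n_zero else None
    if n_true >= 2:
        tw, ew = truth.partial_corr[iu][true_edge], est_w[iu][true_edge]
        if np.std(tw) > 0 and np.std(ew) > 0:
            wc = float(np.corrcoef(tw, ew)[0, 1])
        else:
            wc = None
    else:
        wc = None
    if n_true == 0:
        warnings.warn("truth has no edges; sensitivity undefined (None)")
    return {"sensitivity": sens, "specificity": spec, "weight_correlation": wc}
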