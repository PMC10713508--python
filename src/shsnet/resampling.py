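"""Accuracy and stability diagnostics for estimated networks.

Two resampling schemes, both re-running the full estimation pipeline
(correlation → glasso/EBIC) per replicate:

* nonparametric bootstrap of respondents — per-edge quantile confidence
  intervals and bootstrapped difference tests between edges or centralities;
* case-dropping (sub-setting) bootstrap — networks re-estimated on subsets
  with an increasing proportion of respondents removed; the correlation of
  subset centralities with the original centralities yields the
  correlation-stability (CS) coefficient: the largest drop proportion at
  which that correlation stays ≥ 0.7 with 95% certainty.  A CS below 0.25
  is considered unstable, above 0.5 comfortably stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import correlation_matrix
from .ggm import EstimationConfig, estimate_network
from .metrics import centrality_indices
from .shsq import LikertResponseMatrix

__all__ = [
    "BootstrapEnsemble",
    "StabilityResult",
    "bootstrap_edges",
    "difference_tests",
    "case_drop_stability",
    "cs_coefficient",
    "cs_from_quantile_curve",
]

_INDICES = ("strength", "closeness", "betweenness")


@dataclass
class BootstrapEnsemble:
    labels: list[str]
    weights: np.ndarray  # (B, p, p) replicate weight matrices
    centralities: dict[str, np.ndarray]  # index -> (B, p)
    original_weights: np.ndarray
    original_centralities: pd.DataFrame
    seed: int | None
    config: EstimationConfig
    n_dropped: int = 0

    @property
    def B(self) -> int:
        return self.weights.shape[0]


@dataclass
class StabilityResult:
    proportions: np.ndarray
    correlations: dict[str, np.ndarray]  # index -> (len(proportions), B) matrix
    B_per_level: int
    seed: int | None
    config: EstimationConfig
    n_failed: int = 0


def _fit_once(data: pd.DataFrame, config: EstimationConfig, method: str):
    S = correlation_matrix(data, method=method)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_network(S, n=len(data), config=config)


def bootstrap_edges(
    m: LikertResponseMatrix,
    config: EstimationConfig | None = None,
    B: int = 500,
    seed: int | None = None,
    method: str = "polychoric",
) -> tuple[BootstrapEnsemble, pd.DataFrame]:
    """Nonparametric bootstrap of the edge weights with 95% quantile CIs.

    Respondents are resampled with replacement B times and the full pipeline
    re-estimated per resample.  Replicates where estimation fails (e.g. a
    constant item in the resample) are dropped with a log message; more than
    10% failures is an error.  Returns the ensemble and a per-edge CI table.
    """
    config = config or EstimationConfig()
    if B < 100:
        warnings.warn(f"B = {B} < 100; interval estimates will be coarse")
    rng = np.random.default_rng(seed)
    df = m.to_frame()
    n = len(df)
    original = _fit_once(df, config, method)
    orig_cent = centrality_indices(original).values

    reps, dropped = [], 0
    cents: dict[str, list] = {k: [] for k in _INDICES}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            net = _fit_once(df.iloc[idx], config, method)
        except ValueError as err:
            dropped += 1
            warnings.warn(f"bootstrap replicate {b} dropped: {err}")
            continue
        reps.append(net.weights)
        c = centrality_indices(net).values
        for k in _INDICES:
            cents[k].append(c[k].to_numpy())
    if dropped > 0.10 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed; data too degenerate")

    W = np.stack(reps) if reps else np.empty((0, original.p, original.p))
    ens = BootstrapEnsemble(
        labels=list(original.labels),
        weights=W,
        centralities={k: np.stack(v) if v else np.empty((0, original.p)) for k, v in cents.items()},
        original_weights=original.weights,
        original_centralities=orig_cent,
        seed=seed,
        config=config,
        n_dropped=dropped,
    )

    p = original.p
    iu = np.triu_indices(p, 1)
    lo = np.quantile(W[:, iu[0], iu[1]], 0.025, axis=0)
    hi = np.quantile(W[:, iu[0], iu[1]], 0.975, axis=0)
    ci = pd.DataFrame(
        {
            "node_a": np.asarray(ens.labels)[iu[0]],
            "node_b": np.asarray(ens.labels)[iu[1]],
            "estimate": original.weights[iu],
            "boot_mean": W[:, iu[0], iu[1]].mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return ens, ci


def difference_tests(
    ens: BootstrapEnsemble, alpha: float = 0.05, target: str = "edges"
) -> pd.DataFrame:
    """Bootstrapped difference tests between edge weights or node strengths.

    For each pair of edges (or nodes), the bootstrap distribution of the
    difference is summarised by its (α/2, 1−α/2) quantile interval; the pair
    is flagged "different" iff that interval excludes 0.  Returns a boolean
    DataFrame (the gray/black box matrix of accuracy plots).
    """
    if ens.B < 100:
        warnings.warn("fewer than 100 replicates; difference tests are unreliable")
    if target == "edges":
        p = len(ens.labels)
        iu = np.triu_indices(p, 1)
        vals = ens.weights[:, iu[0], iu[1]]  # (B, E)
        names = [f"{ens.labels[i]}--{ens.labels[j]}" for i, j in zip(*iu)]
    elif target == "centrality":
        vals = ens.centralities["strength"]
        names = list(ens.labels)
    else:
        raise ValueError(f"unknown target {target!r}")
    E = vals.shape[1]
    diff = vals[:, :, None] - vals[:, None, :]  # (B, E, E)
    lo = np.quantile(diff, alpha / 2, axis=0)
    hi = np.quantile(diff, 1 - alpha / 2, axis=0)
    different = (lo > 0) | (hi < 0)
    np.fill_diagonal(different, False)
    return pd.DataFrame(different, index=names, columns=names)


def case_drop_stability(
    m: LikertResponseMatrix,
    config: EstimationConfig | None = None,
    proportions: np.ndarray | None = None,
    B_per_level: int = 50,
    seed: int | None = None,
    method: str = "polychoric",
    min_subset: int = 20,
) -> StabilityResult:
    """Case-dropping bootstrap of the centrality indices.

    For each drop proportion q, ``B_per_level`` subsamples of size
    ⌊(1−q)n⌋ are drawn without replacement, the network re-estimated, and
    each centrality index correlated (Pearson) with the original network's.
    Proportions leaving fewer than ``min_subset`` respondents are truncated
    from the grid with a warning.
    """
    config = config or EstimationConfig()
    if proportions is None:
        proportions = np.round(np.arange(0.05, 0.80, 0.05), 2)
    proportions = np.asarray(sorted(proportions), dtype=float)
    df = m.to_frame()
    n = len(df)
    keep = np.floor((1 - proportions) * n).astype(int) >= min_subset
    if not keep.all():
        warnings.warn(
            f"truncating drop grid: proportions above {proportions[keep].max() if keep.any() else None} "
            f"leave fewer than {min_subset} respondents"
        )
    proportions = proportions[keep]
    if proportions.size == 0:
        raise ValueError("drop grid empty after truncation; sample too small")

    rng = np.random.default_rng(seed)
    original = _fit_once(df, config, method)
    orig_cent = centrality_indices(original).values

    corrs = {k: np.full((len(proportions), B_per_level), np.nan) for k in _INDICES}
    failed = 0
    for qi, q in enumerate(proportions):
        size = int(np.floor((1 - q) * n))
        for b in range(B_per_level):
            idx = rng.choice(n, size=size, replace=False)
            try:
                net = _fit_once(df.iloc[idx], config, method)
            except ValueError:
                failed += 1
                continue
            c = centrality_indices(net).values
            for k in _INDICES:
                a, bvec = orig_cent[k].to_numpy(), c[k].to_numpy()
                if np.std(a) > 0 and np.std(bvec) > 0:
                    corrs[k][qi, b] = np.corrcoef(a, bvec)[0, 1]
                else:
                    corrs[k][qi, b] = 0.0
    return StabilityResult(
        proportions=proportions,
        correlations=corrs,
        B_per_level=B_per_level,
        seed=seed,
        config=config,
        n_failed=failed,
    )


def cs_from_quantile_curve(
    curve: dict[float, float], corr_threshold: float = 0.7
) -> float:
    """CS from a precomputed {drop proportion → correlation quantile} curve.

    The CS-coefficient is the largest proportion whose quantile is still at
    or above the threshold; 0.0 if none qualifies.
    """
    qualifying = [q for q, v in curve.items() if v >= corr_threshold]
    return float(max(qualifying)) if qualifying else 0.0


def cs_coefficient(
    res: StabilityResult,
    corr_threshold: float = 0.7,
    certainty: float = 0.95,
) -> dict[str, float]:
    """Correlation-stability coefficient per centrality index.

    For each index, the empirical (1 − certainty) quantile of the
    subset-vs-original correlation distribution is computed at every drop
    proportion; CS is the largest proportion where it is still
    ≥ ``corr_threshold``.
    """
    out = {}
    for k, mat in res.correlations.items():
        curve = {}
        for qi, q in enumerate(res.proportions):
            vals = mat[qi][~np.isnan(mat[qi])]
            if vals.size == 0:
                continue
            curve[float(q)] = float(np.quantile(vals, 1 - certainty))
        out[k] = cs_from_quantile_curve(curve, corr_threshold)
    return out
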