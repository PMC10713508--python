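"""Two-group network comparison by permutation.

The optimal and suboptimal cohorts get separately estimated networks; to ask
whether they differ beyond sampling noise, respondents are pooled and group
labels permuted (preserving the original group sizes), the two networks are
re-estimated per permutation, and the observed statistic is referred to the
permutation null.  Two statistics are provided because "overall connectivity"
can be read two ways: the absolute difference in global strength
(Σ over pairs of |w_ij|) and the maximum absolute edge difference.  P-values
use the add-one estimator p = (1 + #{perm ≥ obs}) / (1 + n_perm), which can
never be zero and is exactly valid under exchangeability.  Structural
similarity is summarised by the Pearson correlation of the vectorised
weighted adjacency matrices (zeros included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import correlation_matrix
from .ggm import EstimationConfig, PartialCorrelationNetwork, estimate_network
from .shsq import LikertResponseMatrix

__all__ = [
    "ComparisonResult",
    "global_strength",
    "network_comparison_test",
    "adjacency_correlation",
]


@dataclass
class ComparisonResult:
    statistics: list[str]
    observed: dict[str, float]
    p_values: dict[str, float]
    global_strength_a: float
    global_strength_b: float
    adjacency_corr: float
    n_perm: int
    seed: int | None
    null_distributions: pd.DataFrame | None = None
    n_failed_perms: int = 0


def global_strength(net: PartialCorrelationNetwork) -> float:
    """Overall connectivity: sum of |w_ij| over unordered node pairs."""
    iu = np.triu_indices(net.p, 1)
    return float(np.abs(net.weights[iu]).sum())


def adjacency_correlation(
    netA: PartialCorrelationNetwork, netB: PartialCorrelationNetwork
) -> float:
    """Pearson correlation of the two lower-triangle weight vectors (zeros kept)."""
    if list(netA.labels) != list(netB.labels):
        raise ValueError("networks must share labels (same items, same order)")
    iu = np.triu_indices(netA.p, 1)
    a, b = netA.weights[iu], netB.weights[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in an adjacency vector; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _stat_values(
    netA: PartialCorrelationNetwork, netB: PartialCorrelationNetwork
) -> dict[str, float]:
    iu = np.triu_indices(netA.p, 1)
    return {
        "global_strength_diff": abs(global_strength(netA) - global_strength(netB)),
        "max_edge_diff": float(np.abs(netA.weights[iu] - netB.weights[iu]).max()),
    }


def _fit(df: pd.DataFrame, config: EstimationConfig, method: str):
    S = correlation_matrix(df, method=method)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_network(S, n=len(df), config=config)


def network_comparison_test(
    mA: LikertResponseMatrix,
    mB: LikertResponseMatrix,
    config: EstimationConfig | None = None,
    n_perm: int = 1000,
    statistics: tuple[str, ...] = ("global_strength_diff", "max_edge_diff"),
    seed: int | None = None,
    method: str = "polychoric",
    keep_null: bool = False,
) -> ComparisonResult:
    """Permutation network comparison test between two cohorts.

    Group labels are permuted over the pooled respondents with the original
    group sizes preserved exactly; both networks are re-estimated end-to-end
    per permutation.  Permutations where estimation fails are skipped; more
    than 10% failures is an error.
    """
    config = config or EstimationConfig()
    if list(mA.items) != list(mB.items):
        raise ValueError("both groups must measure the same items in the same order")
    known = {"global_strength_diff", "max_edge_diff"}
    if not set(statistics) <= known:
        raise ValueError(f"unknown statistics {set(statistics) - known}")
    nA, nB = mA.n_respondents, mB.n_respondents
    if min(nA, nB) < 20:
        warnings.warn(f"small group sizes ({nA}, {nB}); permutation null may be coarse")

    dfA, dfB = mA.to_frame(), mB.to_frame()
    netA = _fit(dfA, config, method)
    netB = _fit(dfB, config, method)
    observed_all = _stat_values(netA, netB)
    observed = {s: observed_all[s] for s in statistics}

    pooled = pd.concat([dfA, dfB], axis=0, ignore_index=True)
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in statistics}
    null_rows, failed = [], 0
    for _ in range(n_perm):
        perm = rng.permutation(nA + nB)
        try:
            pA = _fit(pooled.iloc[perm[:nA]], config, method)
            pB = _fit(pooled.iloc[perm[nA:]], config, method)
        except ValueError:
            failed += 1
            continue
        vals = _stat_values(pA, pB)
        for s in statistics:
            if vals[s] >= observed[s]:
                counts[s] += 1
        if keep_null:
            null_rows.append({s: vals[s] for s in statistics})
    if failed > 0.10 * n_perm:
        raise RuntimeError(f"{failed}/{n_perm} permutations failed to estimate")
    effective = n_perm - failed
    p_values = {s: (1 + counts[s]) / (1 + effective) for s in statistics}
    try:
        adj_corr = adjacency_correlation(netA, netB)
    except ValueError:  # an empty estimated network leaves the correlation undefined
        adj_corr = float("nan")
    return ComparisonResult(
        statistics=list(statistics),
        observed=observed,
        p_values=p_values,
        global_strength_a=global_strength(netA),
        global_strength_b=global_strength(netB),
        adjacency_corr=adj_corr,
        n_perm=effective,
        seed=seed,
        null_distributions=pd.DataFrame(null_rows) if keep_null else None,
        n_failed_perms=failed,
    )
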