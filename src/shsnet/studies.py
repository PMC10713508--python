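"""Reproducibility and calibration studies.

Functions here recompute, from scratch, the quantities used to validate the
package: the published summary statistics that are recomputable from printed
tables (effect sizes, cohort composition, predictability averages, network
densities), and simulation studies that characterise the estimation
machinery (solver-vs-oracle agreement, edge recovery as a function of sample
size, permutation-test type-I error, MDS configuration recovery).  Both the
acceptance test suite and ``scripts/acceptance.py`` call these.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from scipy import optimize

from . import cohort as cohort_mod
from .association import correlation_matrix
from .comparison import network_comparison_test
from .embedding import ordinal_mds, procrustes_distance
from .ggm import EstimationConfig, estimate_network, glasso_fit, network_summary
from .shsq import cohens_d, pooled_t_from_summaries

__all__ = [
    "load_printed_summaries",
    "recompute_table1_effects",
    "female_percentage",
    "domain_predictability_means",
    "item_network_densities",
    "glasso_oracle_deviation",
    "recovery_study",
    "nct_type_one_error",
    "mds_recovery",
]


def load_printed_summaries() -> dict:
    text = resources.files("shsnet.presets").joinpath("printed_summaries.json").read_text()
    return json.loads(text)


def recompute_table1_effects() -> dict[str, dict[str, float]]:
    """Cohen's d, t, df and p for every numeric variable from printed summaries."""
    summ = load_printed_summaries()
    n1 = summ["group_n"]["optimal"]
    n2 = summ["group_n"]["suboptimal"]
    out = {}
    for var, rec in summ["numeric_variables"].items():
        (m1, s1), (m2, s2) = rec["optimal"], rec["suboptimal"]
        d = cohens_d(m1, s1, n1, m2, s2, n2)
        t, df, p = pooled_t_from_summaries(m1, s1, n1, m2, s2, n2)
        out[var] = {"d": d, "t": t, "df": df, "p": p}
    return out


def female_percentage() -> float:
    """Overall percentage of female respondents from the printed group counts."""
    g = load_printed_summaries()["gender_counts"]
    female = g["optimal"]["female"] + g["suboptimal"]["female"]
    total = female + g["optimal"]["male"] + g["suboptimal"]["male"]
    return 100.0 * female / total


def domain_predictability_means() -> dict[str, float]:
    """Mean of the five printed per-domain predictability values, per population."""
    dp = load_printed_summaries()["domain_predictability"]
    return {
        pop: float(round(np.mean(list(vals.values())), 2)) for pop, vals in dp.items()
    }


def item_network_densities() -> dict[str, float]:
    """Densities implied by the printed edge counts on 25 nodes."""
    rec = load_printed_summaries()["item_network_edges"]
    possible = rec["nodes"] * (rec["nodes"] - 1) // 2
    return {
        "optimal": rec["optimal"] / possible,
        "suboptimal": rec["suboptimal"] / possible,
        "possible_edges": possible,
    }


def _brute_force_glasso(S: np.ndarray, lam: float) -> np.ndarray:
    """Direct numeric maximisation of log det Θ − tr(SΘ) − λΣ_{i≠j}|θ_ij|.

    Independent of the coordinate-descent solver: each off-diagonal is split
    into a positive and a negative part (both bounded at 0), which turns the
    L1 term into a smooth linear one, and the resulting problem is solved by
    L-BFGS-B with exact gradients (∂(−logdet Θ)/∂Θ = −Θ⁻¹).  Practical for
    small p only.
    """
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    n_off = len(iu[0])

    def unpack(x: np.ndarray) -> np.ndarray:
        diag, upos, uneg = x[:p], x[p : p + n_off], x[p + n_off :]
        T = np.zeros((p, p))
        T[iu] = upos - uneg
        T = T + T.T
        T[np.diag_indices(p)] = diag
        return T

    def negobj_grad(x: np.ndarray):
        T = unpack(x)
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return 1e12, np.zeros_like(x)
        f = -(logdet - np.trace(S @ T)) + 2 * lam * (x[p:].sum())
        G = -np.linalg.inv(T) + S  # gradient of the smooth part w.r.t. Θ
        g = np.concatenate([np.diag(G), 2 * G[iu] + 2 * lam, -2 * G[iu] + 2 * lam])
        return f, g

    theta0 = np.linalg.inv(S)
    x0 = np.concatenate(
        [np.diag(theta0), np.clip(theta0[iu], 0, None), np.clip(-theta0[iu], 0, None)]
    )
    bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * n_off)
    res = optimize.minimize(
        negobj_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return unpack(res.x)


def glasso_oracle_deviation(lambdas=(0.0, 0.05, 0.2, 0.4)) -> float:
    """Max |Θ_glasso − Θ_oracle| over small test matrices and a λ grid."""
    S2 = np.array([[1.0, 0.5], [0.5, 1.0]])
    S3 = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, -0.3], [0.2, -0.3, 1.0]])
    config = EstimationConfig(tol=1e-10, max_iter=2000)
    dev = 0.0
    for S in (S2, S3):
        for lam in lambdas:
            theta = glasso_fit(S, lam, config)
            oracle = _brute_force_glasso(S, lam)
            dev = max(dev, float(np.abs(theta - oracle).max()))
    return dev


def recovery_study(
    seed: int = 0,
    n_values: tuple[int, ...] = (250, 1000, 2000),
    replicates: int = 20,
    p: int = 10,
    density: float = 0.2,
    method: str = "polychoric",
) -> dict[int, dict[str, float]]:
    """Mean edge-recovery sensitivity/specificity of the estimator per sample size.

    Each replicate draws a fresh sparse truth, generates an ordinal cohort at
    each n from the same truth, estimates the network and scores recovery.
    """
    rng = np.random.default_rng(seed)
    config = EstimationConfig(n_lambdas=40)
    sums = {n: {"sensitivity": [], "specificity": []} for n in n_values}
    for _ in range(replicates):
        truth_seed = int(rng.integers(2**31))
        truth = cohort_mod.make_truth_network(p=p, density=density, seed=truth_seed)
        for n in n_values:
            pre = cohort_mod.generic_preset(p=p, n=n)
            m = cohort_mod.generate_cohort(truth, pre, seed=int(rng.integers(2**31)))
            S = correlation_matrix(m, method=method)
            net = estimate_network(S, n=n, config=config)
            rec = cohort_mod.recovery_metrics(net, truth)
            sums[n]["sensitivity"].append(rec["sensitivity"])
            sums[n]["specificity"].append(rec["specificity"])
    return {
        n: {k: float(np.mean(v)) for k, v in d.items()} for n, d in sums.items()
    }


def nct_type_one_error(
    seed: int = 0,
    repeats: int = 200,
    n_perm: int = 200,
    n_per_group: int = 200,
    p: int = 5,
    density: float = 0.3,
    alpha: float = 0.05,
    statistic: str = "global_strength_diff",
    truth_seed: int = 314159,
) -> dict[str, float]:
    """Empirical type-I error of the permutation comparison test under the null.

    Both groups are drawn from one generating distribution, so any rejection
    is a false positive.  The generating truth network is a fixed part of the
    study design (``truth_seed``); ``seed`` drives the cohort draws and
    permutations.  Estimation is run at reduced scale (few items, short λ
    path, bounded iterations) — permutation tests are exactly valid for any
    statistic, so the grid coarseness affects power, not level.
    """
    rng = np.random.default_rng(seed)
    truth = cohort_mod.make_truth_network(p=p, density=density, seed=truth_seed)
    # short path / coarse solver tolerance: the permutation null applies the
    # identical procedure to the permuted data, so level is unaffected
    config = EstimationConfig(n_lambdas=5, tol=5e-3, lambda_min_ratio=0.15, max_iter=50)
    rejections = 0
    for _ in range(repeats):
        pre = cohort_mod.generic_preset(p=p, n=n_per_group)
        mA = cohort_mod.generate_cohort(truth, pre, seed=int(rng.integers(2**31)))
        mB = cohort_mod.generate_cohort(truth, pre, seed=int(rng.integers(2**31)))
        res = network_comparison_test(
            mA, mB, config, n_perm=n_perm, statistics=(statistic,),
            seed=int(rng.integers(2**31)), method="pearson",
        )
        if res.p_values[statistic] <= alpha:
            rejections += 1
    rate = rejections / repeats
    return {
        "rate": rate,
        "repeats": repeats,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / repeats)),
    }


def mds_recovery(seed: int = 0, n_points: int = 12) -> dict[str, float]:
    """Recover an exact planar configuration from its distance matrix.

    For distances realisable in the plane, ordinal MDS should reach near-zero
    stress and reproduce the configuration up to rotation/reflection/
    translation/scale.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_points, 2))
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    emb = ordinal_mds(D, dim=2, seed=seed)
    return {
        "stress": emb.stress,
        "procrustes": procrustes_distance(X, emb.coordinates),
        "iterations": emb.iterations,
    }
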