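"""Zero-order association matrices for ordinal items.

Item networks start from a plain (unconditional) correlation matrix among the
25 items.  Because ratings are 5-point ordinal, the default association is
the polychoric correlation — the latent-Gaussian correlation inferred from
the pairwise contingency table by the classical two-step estimator
(thresholds from the margins, then a 1-D likelihood maximisation).  Pearson
and Spearman are available for sensitivity analysis.  Polychoric matrices
need not be positive definite, so an eigenvalue-clipping repair is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .shsq import LikertResponseMatrix

__all__ = [
    "CorrelationMatrix",
    "correlation_matrix",
    "polychoric_pair",
    "nearest_pd",
    "CORRELATION_CAP",
]

CORRELATION_CAP = 0.999  # keeps log-det of downstream models finite
_PD_TOL = 1e-8


@dataclass
class CorrelationMatrix:
    """Labelled symmetric correlation matrix with provenance."""

    labels: list[str]
    values: np.ndarray
    method: str  # pearson | spearman | polychoric
    n_effective: int
    pd_repaired: bool = False

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


# Gauss-Legendre nodes/weights for the correlation-integral form of the
# bivariate normal CDF; 48 points keeps ~1e-10 accuracy for |rho| <= 0.999
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bvn_cdf(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF Φ2(a, b; ρ) at an array of points.

    Uses Φ2(a,b;ρ) = Φ(a)Φ(b) + (2π)⁻¹ ∫₀^ρ (1−r²)^{-1/2}
    exp(−(a²+b²−2abr)/(2(1−r²))) dr, evaluated by Gauss–Legendre quadrature —
    vectorised over all points at a fixed ρ, which is the access pattern of
    the polychoric likelihood.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    base = stats.norm.cdf(a) * stats.norm.cdf(b)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)  # map [-1,1] -> [0, rho]
    w = 0.5 * abs(rho) * _GL_WEIGHTS * np.sign(rho)
    one_m_r2 = 1.0 - r**2
    aa = a[..., None]
    bb = b[..., None]
    integrand = np.exp(
        -(aa**2 + bb**2 - 2.0 * aa * bb * r) / (2.0 * one_m_r2)
    ) / np.sqrt(one_m_r2)
    return base + (integrand @ w) / (2.0 * np.pi)


def _cell_probabilities(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the latent bivariate normal for each cell."""
    ax = np.concatenate([[-8.0], tx, [8.0]])
    ay = np.concatenate([[-8.0], ty, [8.0]])
    A, B = np.meshgrid(ax, ay, indexing="ij")
    F = _bvn_cdf(A, B, rho)
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def polychoric_pair(x, y) -> dict:
    """Two-step polychoric correlation between two ordinal vectors.

    Thresholds come from the marginal cumulative proportions through the
    inverse normal CDF; ρ maximises the multinomial likelihood of the
    contingency table under a latent bivariate normal, constrained to
    (−0.999, 0.999).  Categories that are empty in a margin are collapsed.
    Returns ``{"rho", "thresholds_x", "thresholds_y"}``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise TypeError("x and y must be 1-D ordinal vectors of equal length")
    if not (np.issubdtype(x.dtype, np.number) and np.issubdtype(y.dtype, np.number)):
        raise TypeError("ordinal vectors must be numeric")
    ok = ~(np.isnan(x.astype(float)) | np.isnan(y.astype(float)))
    x, y = x[ok], y[ok]
    cx, cy = np.unique(x), np.unique(y)
    if len(cx) < 2 or len(cy) < 2:
        raise ValueError("each vector needs at least 2 observed categories")
    n = len(x)
    table = np.zeros((len(cx), len(cy)))
    for i, a in enumerate(cx):
        for j, b in enumerate(cy):
            table[i, j] = np.sum((x == a) & (y == b))

    def thresholds(margin_counts: np.ndarray) -> np.ndarray:
        cum = np.cumsum(margin_counts)[:-1] / margin_counts.sum()
        cum = np.clip(cum, 1e-10, 1 - 1e-10)
        return stats.norm.ppf(cum)

    tx = thresholds(table.sum(axis=1))
    ty = thresholds(table.sum(axis=0))

    def negloglik(rho: float) -> float:
        probs = np.clip(_cell_probabilities(tx, ty, rho), 1e-12, None)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-CORRELATION_CAP, CORRELATION_CAP), method="bounded",
        options={"xatol": 1e-6},
    )
    return {"rho": float(res.x), "thresholds_x": tx, "thresholds_y": ty, "n": n}


def correlation_matrix(
    m: LikertResponseMatrix | pd.DataFrame,
    method: str = "polychoric",
    pd_repair: bool = True,
) -> CorrelationMatrix:
    """Pairwise zero-order correlation matrix of the items.

    Missing data are handled pairwise-complete; ``n_effective`` records the
    minimum pairwise n.  Perfectly associated pairs are clipped at ±0.999
    with a degeneracy warning.  If the assembled matrix is not positive
    definite it is repaired by :func:`nearest_pd` and flagged.
    """
    df = m.to_frame() if isinstance(m, LikertResponseMatrix) else m
    labels = list(df.columns)
    data = df.to_numpy(dtype=float)
    n, p = data.shape
    complete = (~np.isnan(data)).sum(axis=0).min()
    if n < 3:
        raise ValueError("need at least 3 respondents for a correlation matrix")
    constant = [labels[j] for j in range(p) if len(np.unique(data[~np.isnan(data[:, j]), j])) < 2]
    if constant:
        raise ValueError(f"constant items cannot be correlated: {constant}")

    if method in ("pearson", "spearman"):
        R = df.corr(method=method, min_periods=2).to_numpy()
        pair_n = (~np.isnan(data[:, None, :]) & ~np.isnan(data[:, :, None])).sum(axis=0)
        n_eff = int(pair_n[np.triu_indices(p, 1)].min()) if p > 1 else n
    elif method == "polychoric":
        R = np.eye(p)
        n_eff = n
        for i in range(p):
            for j in range(i + 1, p):
                ok = ~(np.isnan(data[:, i]) | np.isnan(data[:, j]))
                res = polychoric_pair(data[ok, i], data[ok, j])
                R[i, j] = R[j, i] = res["rho"]
                n_eff = min(n_eff, res["n"])
    else:
        raise ValueError(f"unknown method {method!r}")

    off = ~np.eye(p, dtype=bool)
    if np.any(np.abs(R[off]) > CORRELATION_CAP):
        warnings.warn(
            "perfect or near-perfect association detected; correlations clipped at "
            f"±{CORRELATION_CAP}"
        )
        R[off] = np.clip(R[off], -CORRELATION_CAP, CORRELATION_CAP)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)

    repaired = False
    if np.linalg.eigvalsh(R)[0] < _PD_TOL:
        if not pd_repair:
            raise ValueError("correlation matrix is not positive definite")
        R, _ = nearest_pd(R)
        repaired = True
    return CorrelationMatrix(
        labels=labels, values=R, method=method, n_effective=int(n_eff), pd_repaired=repaired
    )


def nearest_pd(values: np.ndarray, tol: float = _PD_TOL) -> tuple[np.ndarray, float]:
    """Nearest positive-definite correlation-like matrix by eigenvalue clipping.

    Eigenvalues below ``tol`` are raised to ``tol``, the matrix is rebuilt and
    re-scaled to unit diagonal (iterating, since the re-scale can perturb the
    spectrum).  Returns the repaired matrix and its Frobenius distance to the
    input.  Already-PD inputs are returned unchanged with distance 0.
    """
    A = np.asarray(values, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("input must be a symmetric square matrix")
    B = (A + A.T) / 2
    if np.linalg.eigvalsh(B)[0] >= tol:
        return A.copy(), 0.0
    for _ in range(100):
        w, V = np.linalg.eigh(B)
        if w[0] >= tol:
            break
        # clip above tol: re-scaling to unit diagonal shrinks the spectrum slightly
        w = np.clip(w, 2 * tol, None)
        B = (V * w) @ V.T
        d = np.sqrt(np.diag(B))
        B = B / np.outer(d, d)
        B = (B + B.T) / 2
        np.fill_diagonal(B, 1.0)
    return B, float(np.linalg.norm(B - A, "fro"))
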