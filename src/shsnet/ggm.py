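"""Sparse Gaussian graphical model estimation.

Zeros of the precision matrix Θ = Σ⁻¹ of a multivariate Gaussian encode
conditional independence, and the scaled negative off-diagonals
ρ_ij = −θ_ij / √(θ_ii θ_jj) are partial correlations — the edge weights of
the networks estimated here.  Θ is estimated by the graphical lasso
(L1-penalised Gaussian log-likelihood, off-diagonal penalty) along a
descending log-spaced λ path, and the penalty is selected by minimising the
extended Bayesian Information Criterion with hyperparameter γ (default 0.5):

    EBIC(λ) = −2ℓ(Θ̂) + E log n + 4 γ E log p

with ℓ = (n/2)(log det Θ − tr(SΘ)) and E the number of nonzero off-diagonal
pairs.  Ties are broken toward larger λ (sparser model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning

from .association import CorrelationMatrix

__all__ = [
    "EstimationConfig",
    "PartialCorrelationNetwork",
    "NetworkSummary",
    "glasso_fit",
    "lambda_path",
    "ebic_score",
    "estimate_network",
    "network_summary",
    "precision_to_partial",
]

_EDGE_EPS = 1e-8  # below this magnitude a precision off-diagonal counts as zero


@dataclass
class EstimationConfig:
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    penalize_diagonal: bool = False
    tol: float = 1e-4
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.penalize_diagonal:
            raise NotImplementedError(
                "diagonal penalisation is not supported; the unpenalised diagonal "
                "keeps the lambda=0 limit exact"
            )


@dataclass
class PartialCorrelationNetwork:
    """Regularised partial-correlation network with its provenance."""

    labels: list[str]
    weights: np.ndarray  # symmetric, zero diagonal
    precision: np.ndarray  # selected regularised precision (correlation scale)
    lambda_: float
    ebic: float
    n: int
    provenance: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.labels)

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.p, 1)
        w = self.weights[iu]
        keep = w != 0
        return pd.DataFrame(
            {
                "node_a": np.asarray(self.labels)[iu[0][keep]],
                "node_b": np.asarray(self.labels)[iu[1][keep]],
                "weight": w[keep],
            }
        )

    def to_graph(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.labels)
        for _, row in self.edge_list().iterrows():
            G.add_edge(row.node_a, row.node_b, weight=float(row.weight),
                       absweight=abs(float(row.weight)))
        return G


@dataclass
class NetworkSummary:
    edge_count: int
    possible_edges: int
    density: float
    mean_abs_nonzero_weight: float
    empty: bool = False


def _as_matrix(S) -> np.ndarray:
    return S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)


def glasso_fit(S, lam: float, config: EstimationConfig | None = None) -> np.ndarray:
    """Graphical-lasso precision estimate at a single penalty λ.

    Maximises log det Θ − tr(SΘ) − λ Σ_{i≠j} |θ_ij| over positive-definite Θ.
    At λ = 0 this is the unpenalised Gaussian MLE Θ = S⁻¹.
    """
    config = config or EstimationConfig()
    Smat = _as_matrix(S)
    if np.linalg.eigvalsh(Smat)[0] <= 0:
        raise ValueError(
            "S is not positive definite; repair it first (association.nearest_pd)"
        )
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        theta = np.linalg.inv(Smat)
    else:
        with warnings.catch_warnings():
            # the solver warns whenever the final dual gap misses tol even by
            # 1e-6-level slack; that is irrelevant at EBIC-selection precision
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            _, theta = _sk_glasso(
                Smat, alpha=lam, tol=config.tol, enet_tol=config.tol,
                max_iter=config.max_iter,
            )
    theta = (theta + theta.T) / 2
    return theta


def penalised_objective(theta: np.ndarray, S, lam: float) -> float:
    """log det Θ − tr(SΘ) − λ Σ_{i≠j}|θ_ij| (the criterion glasso maximises)."""
    Smat = _as_matrix(S)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = theta[~np.eye(theta.shape[0], dtype=bool)]
    return float(logdet - np.trace(Smat @ theta) - lam * np.abs(off).sum())


def lambda_path(S, config: EstimationConfig | None = None) -> np.ndarray:
    """Descending log-spaced penalty path from λ_max = max |s_ij| (i≠j)."""
    config = config or EstimationConfig()
    Smat = _as_matrix(S)
    p = Smat.shape[0]
    off = Smat[~np.eye(p, dtype=bool)]
    lam_max = float(np.abs(off).max()) if off.size else 0.0
    if lam_max == 0:
        warnings.warn("all off-diagonal correlations are zero; single-point path {0}")
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)


def _count_edges(theta: np.ndarray) -> int:
    p = theta.shape[0]
    iu = np.triu_indices(p, 1)
    return int(np.count_nonzero(np.abs(theta[iu]) > _EDGE_EPS))


def ebic_score(theta: np.ndarray, S, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fitted precision matrix (smaller is better)."""
    Smat = _as_matrix(S)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("theta must be positive definite")
    p = theta.shape[0]
    ll = 0.5 * n * (logdet - np.trace(Smat @ theta))
    E = _count_edges(theta)
    return float(-2 * ll + E * np.log(n) + 4 * gamma * E * np.log(p))


def precision_to_partial(theta: np.ndarray) -> np.ndarray:
    """Partial correlations ρ_ij = −θ_ij / √(θ_ii θ_jj); zero diagonal."""
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    pc = (pc + pc.T) / 2
    np.fill_diagonal(pc, 0.0)
    pc[np.abs(pc) <= _EDGE_EPS] = 0.0
    return pc


def estimate_network(
    S: CorrelationMatrix,
    n: int,
    config: EstimationConfig | None = None,
) -> PartialCorrelationNetwork:
    """EBIC-selected graphical-lasso partial-correlation network.

    Fits the glasso along the λ path, scores each model by EBIC at the
    configured γ, keeps the minimiser (ties toward larger λ) and converts the
    selected precision to partial correlations.  Deterministic: identical
    inputs give bit-identical output.
    """
    config = config or EstimationConfig()
    Smat = _as_matrix(S)
    p = Smat.shape[0]
    if n < p:
        warnings.warn(f"n = {n} < p = {p}; estimates may be unstable")
    labels = (
        list(S.labels) if isinstance(S, CorrelationMatrix) else [f"V{i+1}" for i in range(p)]
    )
    path = lambda_path(S, config)
    best = None
    failed = 0
    for lam in path:  # descending λ, strict improvement => ties keep sparser model
        try:
            theta = glasso_fit(Smat, float(lam), config)
        except FloatingPointError:
            # near-singular S (e.g. polychoric at n < p) can break the solver
            # at the weak-penalty end of the path; those models would be wildly
            # overfit anyway, so they are skipped rather than aborting the path
            failed += 1
            continue
        score = ebic_score(theta, Smat, n, config.gamma)
        if best is None or score < best[0] - 1e-12:
            best = (score, float(lam), theta)
    if best is None:
        raise RuntimeError("graphical lasso failed at every penalty on the path")
    if failed:
        warnings.warn(
            f"{failed}/{len(path)} path penalties skipped (ill-conditioned solve)"
        )
    score, lam_sel, theta_sel = best
    weights = precision_to_partial(theta_sel)
    prov = {"correlation_method": getattr(S, "method", "unknown"), "config": asdict(config)}
    return PartialCorrelationNetwork(
        labels=labels, weights=weights, precision=theta_sel,
        lambda_=lam_sel, ebic=score, n=int(n), provenance=prov,
    )


def network_summary(
    net: PartialCorrelationNetwork, weight_mean: str = "abs_nonzero"
) -> NetworkSummary:
    """Edge count, density and mean edge weight of a network.

    ``weight_mean`` controls the mean-edge-weight convention:
    ``abs_nonzero`` (default) averages |w| over nonzero edges; ``signed_nonzero``
    averages signed weights over nonzero edges; ``abs_all`` averages |w| over
    all p(p−1)/2 pairs.
    """
    p = net.p
    iu = np.triu_indices(p, 1)
    w = net.weights[iu]
    nz = w[w != 0]
    possible = p * (p - 1) // 2
    if weight_mean == "abs_nonzero":
        mean_w = float(np.abs(nz).mean()) if nz.size else 0.0
    elif weight_mean == "signed_nonzero":
        mean_w = float(nz.mean()) if nz.size else 0.0
    elif weight_mean == "abs_all":
        mean_w = float(np.abs(w).mean()) if w.size else 0.0
    else:
        raise ValueError(f"unknown weight_mean {weight_mean!r}")
    return NetworkSummary(
        edge_count=int(nz.size),
        possible_edges=possible,
        density=float(nz.size / possible) if possible else 0.0,
        mean_abs_nonzero_weight=mean_w,
        empty=nz.size == 0,
    )
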