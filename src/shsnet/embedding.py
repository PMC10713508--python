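"""Node-placement geometry: ordinal (non-metric) MDS and a force-directed layout.

Ordinal MDS places nodes in the plane so that the rank order of the input
dissimilarities is respected as far as possible.  The implementation is
standard Kruskal/SMACOF: disparities are fitted each cycle by isotonic
regression of the configuration distances on the dissimilarity order,
rescaled to the distances' norm, and the configuration is updated by the
Guttman transform.  Fit is reported as Kruskal stress-1,

    stress = sqrt( Σ (d_ij − d̂_ij)² / Σ d_ij² ),

together with the Shepard triples (dissimilarity, distance, disparity).
Stress is non-increasing across iterations by the majorisation argument and
this is asserted at run time.  The Fruchterman–Reingold layout is delegated
to networkx with |w| as attraction strength and a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .association import CorrelationMatrix
from .ggm import PartialCorrelationNetwork

__all__ = [
    "EmbeddingResult",
    "corr_to_dissimilarity",
    "ordinal_mds",
    "fr_layout",
    "procrustes_distance",
]


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (p, dim)
    stress: float  # Kruskal stress-1
    shepard: pd.DataFrame  # columns: dissimilarity, distance, disparity
    iterations: int
    converged: bool
    seed: int | None


def corr_to_dissimilarity(R: CorrelationMatrix | np.ndarray, signed: bool = False) -> np.ndarray:
    """d_ij = sqrt(1 − |r_ij|) (default) or sqrt(1 − r_ij) with ``signed=True``.

    The absolute transform treats strong negative associations as proximity,
    matching connectivity semantics; the signed variant keeps anticorrelated
    nodes far apart.
    """
    r = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    d = np.sqrt(np.clip(1.0 - (r if signed else np.abs(r)), 0.0, None))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def _pairwise_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centred squared D."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


def ordinal_mds(
    D: np.ndarray,
    dim: int = 2,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> EmbeddingResult:
    """Non-metric MDS by stress majorisation with isotonic disparities.

    The start is the deterministic classical-MDS configuration, so identical
    inputs give identical output; ``seed`` only perturbs degenerate
    (rank-deficient) starts.  Raises on asymmetric input; if ``max_iter`` is
    reached before the stress decrease falls below ``tol`` the result is
    returned with ``converged=False``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be a symmetric square dissimilarity matrix")
    if (D < 0).any() or not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must be non-negative with zero diagonal")
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")

    X = _classical_mds(D, dim)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < min(dim, n - 1):
        rng = np.random.default_rng(seed)
        X = X + 1e-6 * rng.standard_normal(X.shape)

    iso = IsotonicRegression(increasing=True)
    prev_stress = np.inf
    stress = np.inf
    dhat_full = np.zeros_like(D)
    it = 0
    for it in range(1, max_iter + 1):
        dist = _pairwise_distances(X)
        dvec = dist[iu]
        # monotone regression of distances on the dissimilarity rank order
        dhat = np.empty_like(dvec)
        dhat[order] = iso.fit_transform(np.arange(len(delta)), dvec[order])
        denom = float(dvec @ dvec)
        if denom == 0:
            stress = 0.0
            break
        dhat *= np.sqrt(denom / float(dhat @ dhat))
        stress = float(np.sqrt(np.sum((dvec - dhat) ** 2) / denom))
        if stress > prev_stress + 1e-12:
            raise AssertionError(
                f"stress increased across majorisation iterations ({prev_stress} -> {stress})"
            )
        if prev_stress - stress < tol:
            prev_stress = stress
            break
        prev_stress = stress
        # Guttman transform with the fitted disparities
        dhat_full[iu] = dhat
        dhat_full.T[iu] = dhat
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat_full / np.where(dist > 0, dist, 1.0), 0.0)
        Bmat = -ratio
        np.fill_diagonal(Bmat, ratio.sum(axis=1))
        X = Bmat @ X / n
    dist = _pairwise_distances(X)
    dvec = dist[iu]
    dhat = np.empty_like(dvec)
    dhat[order] = iso.fit_transform(np.arange(len(delta)), dvec[order])
    if dvec @ dvec > 0 and dhat @ dhat > 0:
        dhat *= np.sqrt(float(dvec @ dvec) / float(dhat @ dhat))
    shepard = pd.DataFrame(
        {"dissimilarity": delta, "distance": dvec, "disparity": dhat}
    ).sort_values("dissimilarity", kind="stable", ignore_index=True)
    return EmbeddingResult(
        coordinates=X,
        stress=stress if np.isfinite(stress) else 0.0,
        shepard=shepard,
        iterations=it,
        converged=prev_stress - stress < tol or stress == 0.0,
        seed=seed,
    )


def fr_layout(
    net: PartialCorrelationNetwork, seed: int = 0, iterations: int = 100
) -> pd.DataFrame:
    """Fruchterman–Reingold coordinates with |w| as attraction; seeded."""
    G = net.to_graph()
    pos = nx.spring_layout(G, weight="absweight", seed=seed, iterations=iterations)
    coords = pd.DataFrame(
        [(node, xy[0], xy[1]) for node, xy in pos.items()], columns=["node", "x", "y"]
    ).set_index("node").loc[list(net.labels)]
    if not np.isfinite(coords.to_numpy()).all():
        raise RuntimeError("non-finite layout coordinates")
    return coords


def procrustes_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """Disparity after optimal translation/rotation/reflection/scaling.

    Normalised Procrustes disparity between two configurations of the same
    point set (scipy convention: sum of squared residuals after alignment of
    unit-norm centred configurations).
    """
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(X, Y)
    return float(disparity)
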