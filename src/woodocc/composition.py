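"""Assemblage composition: binary Bray-Curtis dissimilarity, non-metric
multidimensional scaling (NMDS, 3 axes) on a representative subsample of
simulated assemblages, and 89% normal-theory ellipses for plotting groups.

The dissimilarity is the Sorensen (binary Bray-Curtis) form
d = (b + c) / (2a + b + c), with a the shared presences and b, c the
presences unique to each assemblage. NMDS minimizes Kruskal stress-1 over
monotone-regressed disparities; as a rank-based method its result depends
only on the ordering of the dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.manifold import smacof

__all__ = [
    "OrdinationResult",
    "binary_bray_curtis",
    "drop_empty_rows",
    "subsample_representative",
    "nmds",
    "ellipse_89",
    "Ellipse",
]

logger = logging.getLogger(__name__)


def binary_bray_curtis(presence: np.ndarray) -> np.ndarray:
    """Pairwise Sorensen dissimilarity matrix of a binary presence matrix.

    Rows with no presences at all make the index undefined against each
    other; remove them first (see :func:`drop_empty_rows`).
    """
    X = np.asarray(presence)
    if X.ndim != 2:
        raise ValueError("presence must be a 2-D matrix")
    if not np.all(np.isin(np.unique(X), [0, 1])):
        raise ValueError("presence matrix must be binary (0/1)")
    if np.any(X.sum(axis=1) == 0):
        raise ValueError(
            "all-zero assemblage rows present; drop them before computing "
            "dissimilarities (drop_empty_rows)"
        )
    # scipy's 'dice' distance is exactly (b + c) / (2a + b + c)
    return squareform(pdist(X.astype(bool), metric="dice"))


def drop_empty_rows(presence: np.ndarray) -> tuple[np.ndarray, int]:
    """Remove richness-0 assemblages; returns (kept rows, number dropped)."""
    X = np.asarray(presence)
    keep = X.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d empty assemblages before ordination", n_dropped)
    return X[keep], n_dropped


def subsample_representative(
    presence: np.ndarray, fraction: float = 0.10, seed: int = 0
) -> np.ndarray:
    """Uniform random subset of assemblage rows, without replacement.

    Size is ``round(fraction * n)``; a fraction of 0.10 of 20,000 simulated
    assemblages gives the 2,000 used for ordination.
    """
    X = np.asarray(presence)
    if X.shape[0] == 0:
        raise ValueError("empty ensemble")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = int(round(fraction * X.shape[0]))
    rng = np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=n, replace=False)
    return X[idx]


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # (n, k), centred at the origin
    stress: float  # Kruskal stress-1
    converged: bool
    n_restarts_used: int


def nmds(
    dissimilarity: np.ndarray,
    k: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    One run starts from the classical (Torgerson) metric-MDS configuration;
    the remaining ``n_restarts - 1`` runs start at random. The best (lowest
    stress) solution is kept and centred. Stress conventions: < 0.05
    excellent, < 0.1 good, < 0.2 usable.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity must have a zero diagonal")
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows for a {k}-axis ordination")
    off = D[~np.eye(n, dtype=bool)]
    if np.ptp(off) < 1e-12:
        raise ValueError(
            "all dissimilarities are equal; the ordination is non-informative"
        )

    # classical-MDS start: double-centred squared dissimilarities
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1][:k]
    init = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))

    rng = np.random.default_rng(seed)
    best_pos, best_stress = None, np.inf
    for r in range(max(1, n_restarts)):
        start = init if r == 0 else rng.normal(size=(n, k))
        pos, stress, n_iter = smacof(
            D,
            metric=False,
            n_components=k,
            init=start,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=0,
            normalized_stress=True,
            return_n_iter=True,
        )
        if stress < best_stress:
            best_pos, best_stress = pos, float(stress)
            best_iter = n_iter
    best_pos = best_pos - best_pos.mean(axis=0)
    return OrdinationResult(
        coordinates=best_pos,
        stress=best_stress,
        converged=best_iter < max_iter,
        n_restarts_used=max(1, n_restarts),
    )


@dataclass
class Ellipse:
    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,) lengths, major first
    angle: float  # radians, orientation of the major axis
    degenerate: bool


def ellipse_89(points: np.ndarray, level: float = 0.89) -> Ellipse:
    """Normal-theory coverage ellipse of a 2-D point cloud.

    The ellipse is the contour of the fitted bivariate normal at the
    chi-square(2 df) quantile of ``level``; for large normal samples it
    contains ~89% of the points at the default level. Collinear point sets
    yield a flagged degenerate ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(evals.min() <= 1e-12 * max(evals.max(), 1.0))
    r2 = chi2.ppf(level, df=2)
    semi = np.sqrt(np.clip(evals, 0.0, None) * r2)[::-1]  # major first
    major = evecs[:, -1]
    angle = float(np.arctan2(major[1], major[0]))
    return Ellipse(center=center, semi_axes=semi, angle=angle, degenerate=degenerate)
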