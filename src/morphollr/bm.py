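"""Multivariate Brownian-motion rate matrices on a phylogeny.

Under BM with rate matrix C (m x m, score-units^2/My), tip values are
matrix-normal: rows (species) covary by the tree's shared branch lengths
C_tree, columns (axes) by C.  The root state is the GLS mean; the fitted C
defines a Gaussian distribution of species in morphospace centered at the
root, whose Mahalanobis contours give the 95/99% bands where species are
expected to lie if evolution follows BM at the observed rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .io import PhyloTree

__all__ = [
    "RateMatrix",
    "MorphospaceDistribution",
    "fit_bm_rate_matrix",
    "ancestral_states",
    "bm_tip_distribution",
    "ci_contour",
    "ContourEllipse",
    "simulate_bm_tips",
]


@dataclass
class RateMatrix:
    C: np.ndarray        # (m, m) symmetric PSD evolutionary rate matrix
    root: np.ndarray     # (m,) ancestral (GLS) state
    m: int
    loglik: float
    divisor: str = "ml"  # "ml" (n) or "reml" (n-1)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("rate matrix must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("rate matrix must be positive semidefinite")
        self.C = (C + C.T) / 2


def fit_bm_rate_matrix(
    scores: np.ndarray,
    tree: PhyloTree | np.ndarray,
    method: str = "ml",
) -> RateMatrix:
    """ML (or REML) fit of the BM rate matrix to tip scores.

    Root state is the GLS mean a = (1' Cinv 1)^-1 1' Cinv Y; the rate matrix
    is C = (Y - 1a')' Ctree^-1 (Y - 1a') / n  (divisor n-1 for REML).  The
    log-likelihood is that of the matrix-normal BM model at the estimate.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    if n <= m:
        warnings.warn(f"n={n} <= m={m}: rate matrix will be rank-deficient")
    Ct = tree.vcv() if isinstance(tree, PhyloTree) else np.asarray(tree, dtype=float)
    L = np.linalg.cholesky(Ct)
    Yw = scipy.linalg.solve_triangular(L, Y, lower=True)
    ones_w = scipy.linalg.solve_triangular(L, np.ones((n, 1)), lower=True)
    a, *_ = np.linalg.lstsq(ones_w, Yw, rcond=None)
    Rw = Yw - ones_w @ a
    div = n if method == "ml" else n - 1
    C = Rw.T @ Rw / div
    C = (C + C.T) / 2
    # matrix-normal log-likelihood at the ML estimates
    sign, logdet_Ct = np.linalg.slogdet(Ct)
    evals = np.linalg.eigvalsh(C)
    pos = evals[evals > 1e-300]
    logdet_C = float(np.log(pos).sum()) if pos.size else -np.inf
    tr_term = n * m if method == "ml" else (n - 1) * m
    ll = -0.5 * (n * m * np.log(2 * np.pi) + m * logdet_Ct + n * logdet_C + tr_term)
    return RateMatrix(C=C, root=a.ravel(), m=m, loglik=float(ll), divisor=method)


def ancestral_states(
    values: np.ndarray,
    tree: PhyloTree,
    node=None,
    taxa: list[str] | None = None,
) -> np.ndarray:
    """GLS/ML ancestral state estimate under BM for an internal node.

    ``node`` may be a dendropy node (e.g. from ``tree.mrca_node``) or None
    for the root.  The root estimate is the GLS mean; internal nodes use the
    conditional expectation given the tips:
    a + c_v' Ctree^-1 (Y - 1 a'), with c_v[i] the depth of MRCA(node, tip i).
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    order = taxa if taxa is not None else tree.taxa
    if len(order) != n:
        raise ValueError("row count does not match taxon count")
    Ct = tree.vcv(order=order)
    L = np.linalg.cholesky(Ct)
    Yw = scipy.linalg.solve_triangular(L, Y, lower=True)
    ones_w = scipy.linalg.solve_triangular(L, np.ones((n, 1)), lower=True)
    a, *_ = np.linalg.lstsq(ones_w, Yw, rcond=None)
    if node is None or node is tree.root:
        return a.ravel()
    cv = tree.node_tip_covariances(node)
    if taxa is not None:
        idx = {t: i for i, t in enumerate(tree.taxa)}
        cv = cv[[idx[t] for t in order]]
    resid = Y - np.ones((n, 1)) @ a
    w = np.linalg.solve(Ct, resid)
    return a.ravel() + cv @ w


@dataclass
class MorphospaceDistribution:
    """Gaussian distribution of a BM tip in morphospace."""

    mean: np.ndarray    # (m',)
    cov: np.ndarray     # (m', m') = depth * C marginal block
    axes: list[int]
    depth: float

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(points, dtype=float)) - self.mean
        sol = np.linalg.solve(self.cov, X.T)
        return np.einsum("ij,ji->i", X, sol)

    def pdf(self, points: np.ndarray) -> np.ndarray:
        m = len(self.mean)
        sign, logdet = np.linalg.slogdet(self.cov)
        d2 = self.mahalanobis_sq(points)
        return np.exp(-0.5 * (m * np.log(2 * np.pi) + logdet + d2))


def bm_tip_distribution(
    rm: RateMatrix, depth: float, axes: list[int] | None = None
) -> MorphospaceDistribution:
    """Distribution of a tip at root-to-tip distance ``depth``: Gaussian with
    mean = root state and covariance = depth x C, marginalized to ``axes``."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    axes = list(range(rm.m)) if axes is None else list(axes)
    if not axes:
        raise ValueError("axes must be non-empty")
    idx = np.asarray(axes)
    return MorphospaceDistribution(
        mean=rm.root[idx],
        cov=depth * rm.C[np.ix_(idx, idx)],
        axes=axes,
        depth=float(depth),
    )


@dataclass
class ContourEllipse:
    center: np.ndarray
    semi_axes: np.ndarray   # lengths of the two principal semi-axes
    angle_deg: float        # orientation of the major axis
    level: float
    radius_sq: float        # chi-square quantile used


def ci_contour(dist: MorphospaceDistribution, level: float):
    """Confidence contour of the tip distribution at probability ``level``.

    Returns ``(contour, inside)`` where ``inside(points)`` is True for points
    whose squared Mahalanobis distance is at most the chi-square quantile with
    m' degrees of freedom; for 2-D marginals ``contour`` is a
    :class:`ContourEllipse` (center, semi-axis lengths, orientation), for 1-D
    an interval, otherwise None (membership only).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = len(dist.mean)
    if np.linalg.matrix_rank(dist.cov) < m:
        raise np.linalg.LinAlgError("singular covariance; contour undefined")
    r2 = float(chi2.ppf(level, df=m))

    def inside(points: np.ndarray) -> np.ndarray:
        return dist.mahalanobis_sq(points) <= r2

    contour = None
    if m == 1:
        half = np.sqrt(r2 * dist.cov[0, 0])
        contour = (float(dist.mean[0] - half), float(dist.mean[0] + half))
    elif m == 2:
        evals, evecs = np.linalg.eigh(dist.cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        contour = ContourEllipse(
            center=dist.mean.copy(),
            semi_axes=np.sqrt(r2 * evals),
            angle_deg=float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))),
            level=level,
            radius_sq=r2,
        )
    return contour, inside


def _psd_factor(M: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(np.asarray(M, dtype=float))
    evals = np.clip(evals, 0.0, None)
    return evecs * np.sqrt(evals)


def simulate_bm_tips(
    rm: RateMatrix,
    tree: PhyloTree | np.ndarray,
    n_reps: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Simulate replicate tip scores under the matrix-normal BM model.

    Returns an (n_reps, n_tips, m) array: each replicate is
    root + L_tree Z L_C', Z i.i.d. standard normal, so rows covary by the
    tree and columns by the rate matrix.
    """
    Ct = tree.vcv() if isinstance(tree, PhyloTree) else np.asarray(tree, dtype=float)
    n = Ct.shape[0]
    Lt = _psd_factor(Ct)
    Lc = _psd_factor(rm.C)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_reps, n, rm.m))
    return rm.root + Lt @ Z @ Lc.T
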