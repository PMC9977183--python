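"""Ordinations of species-mean shapes: PCA, phylogenetic PCA, and
phylogenetically aligned component analysis (PACA).

All three are rigid rotations of the same tangent-space data and differ only
in what the axes optimize: PCA maximizes total variance, pPCA estimates the
covariance in the GLS metric (weighting species by the inverse BM covariance,
centering on the inferred root state), and PACA orders axes by the amount of
phylogenetic signal they carry.  On a star phylogeny all three coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import gaussian_kde

from .io import PhyloTree

__all__ = ["Ordination", "pca", "phylo_pca", "paca", "project_specimens", "family_density"]


@dataclass
class Ordination:
    vectors: np.ndarray        # (k, m) columns; orthonormal in Euclid metric
    scores: np.ndarray         # (n, m)
    var_fraction: np.ndarray   # (m,)
    center: np.ndarray         # (k,)
    method: str                # pca | ppca | paca
    transform_applied: bool = False

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def _orient(vectors: np.ndarray) -> np.ndarray:
    """Sign convention: largest-magnitude loading of each axis positive."""
    V = vectors.copy()
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def pca(Y: np.ndarray) -> Ordination:
    """Ordinary principal component analysis of species means.

    Eigen-decomposition of the sample covariance of mean-centered Y; scores
    are centered data on the eigenvectors, var_fraction the normalized
    eigenvalues.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    center = Y.mean(axis=0)
    Yc = Y - center
    # SVD for numerical stability; eigenvalues of cov = s^2/(n-1)
    _, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    m = min(n - 1, Y.shape[1])
    vectors = _orient(Vt[:m].T)
    eigvals = (s[:m] ** 2) / (n - 1)
    total = (Yc**2).sum() / (n - 1)
    return Ordination(
        vectors=vectors,
        scores=Yc @ vectors,
        var_fraction=eigvals / total,
        center=center,
        method="pca",
    )


def phylo_pca(
    Y: np.ndarray,
    tree: PhyloTree | np.ndarray,
    gls_center: bool = True,
    transform: bool = True,
) -> Ordination:
    """Phylogenetic PCA (GLS-centered, optionally phylogenetically transformed).

    The covariance is estimated in the GLS metric, S = Yc' Cinv Yc / (n-1),
    centered on the GLS mean (the BM root estimate).  With ``transform`` the
    scores are computed from whitened residuals L^-1 Yc, so score distances
    are independent of phylogeny; otherwise plain centered data are projected.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    C = tree.vcv() if isinstance(tree, PhyloTree) else np.asarray(tree, dtype=float)
    L = np.linalg.cholesky(C)
    ones = np.ones((n, 1))
    ones_w = scipy.linalg.solve_triangular(L, ones, lower=True)
    Yw = scipy.linalg.solve_triangular(L, Y, lower=True)
    if gls_center:
        a, *_ = np.linalg.lstsq(ones_w, Yw, rcond=None)
        center = a.ravel()
    else:
        center = Y.mean(axis=0)
    Yc = Y - center
    Ycw = scipy.linalg.solve_triangular(L, Yc, lower=True)
    S = Ycw.T @ Ycw / (n - 1)
    eigvals, vecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1][: min(n - 1, k)]
    eigvals = np.maximum(eigvals[order], 0.0)
    vectors = _orient(vecs[:, order])
    data = Ycw if transform else Yc
    scores = data @ vectors
    return Ordination(
        vectors=vectors,
        scores=scores,
        var_fraction=eigvals / eigvals.sum() if eigvals.sum() > 0 else eigvals,
        center=center,
        method="ppca",
        transform_applied=transform,
    )


def paca(Y: np.ndarray, tree: PhyloTree | np.ndarray) -> Ordination:
    """Phylogenetically aligned component analysis.

    Axes maximize the covariation between the centered data and phylogenetic
    signal: eigenvectors of Yc' A Yc with alignment matrix A = C_tree, ordered
    by signal explained.  On a star tree (C ∝ I) this reduces to PCA.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    C = tree.vcv() if isinstance(tree, PhyloTree) else np.asarray(tree, dtype=float)
    center = Y.mean(axis=0)
    Yc = Y - center
    M = Yc.T @ C @ Yc
    eigvals, vecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1][: min(n - 1, k)]
    eigvals = np.maximum(eigvals[order], 0.0)
    vectors = _orient(vecs[:, order])
    scores = Yc @ vectors
    # fraction of tip variance carried by each aligned axis
    tip_var = (scores**2).sum(axis=0)
    total = (Yc**2).sum()
    return Ordination(
        vectors=vectors,
        scores=scores,
        var_fraction=tip_var / total if total > 0 else tip_var,
        center=center,
        method="paca",
    )


def phylo_signal_fraction(ord_: Ordination, Yc_or_Y: np.ndarray, C: np.ndarray,
                          axis: int = 0) -> float:
    """Fraction of total phylogenetic signal (tr of Yc' C Yc) explained by
    one ordination axis; used to compare PACA against PCA."""
    Y = np.asarray(Yc_or_Y, dtype=float)
    Yc = Y - ord_.center
    v = ord_.vectors[:, axis]
    num = float(v @ Yc.T @ C @ Yc @ v)
    den = float(np.trace(Yc.T @ C @ Yc))
    return num / den


def project_specimens(ord_: Ordination, specimens: np.ndarray) -> np.ndarray:
    """Project tangent vectors (same basis as the ordination input) into the
    ordination: scores = (specimen - center) @ vectors."""
    X = np.atleast_2d(np.asarray(specimens, dtype=float))
    if X.shape[1] != ord_.vectors.shape[0]:
        raise ValueError(
            f"specimen dimension {X.shape[1]} does not match ordination basis "
            f"{ord_.vectors.shape[0]}"
        )
    return (X - ord_.center) @ ord_.vectors


def family_density(
    scores: np.ndarray,
    species_ids: list[str],
    family_of: dict[str, str],
    grid: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Weighted kernel density of specimen scores along one axis, per family.

    Each specimen is weighted by 1/(number of specimens of its species), so
    well-sampled species do not dominate their family's density.  Bandwidth
    is Silverman's rule on the weighted sample; densities integrate to 1
    within each family.  Returns {family: (grid, density)}.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if len(x) != len(species_ids):
        raise ValueError("one species label per score required")
    sp = np.asarray(species_ids)
    counts = {s: int((sp == s).sum()) for s in set(species_ids)}
    w = np.array([1.0 / counts[s] for s in species_ids])
    fams = np.array([family_of[s] for s in species_ids])
    if grid is None:
        # pad generously: Silverman bandwidths on spread-out data are wide
        pad = 0.15 * (x.max() - x.min() + 1e-12) + 3.0 * x.std()
        grid = np.linspace(x.min() - pad, x.max() + pad, 1024)
    out = {}
    for fam in dict.fromkeys(fams.tolist()):
        mask = fams == fam
        xs, ws = x[mask], w[mask]
        if len(np.unique(xs)) == 1:
            # degenerate: all mass at one point; return a spike
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - xs[0]))] = 1.0 / (grid[1] - grid[0])
            out[fam] = (grid, dens)
            continue
        kde = gaussian_kde(xs, weights=ws, bw_method="silverman")
        out[fam] = (grid, kde(grid))
    return out
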