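"""Phylogenetic generalized least squares under Brownian motion, with
residual-randomization (RRPP) significance and effect sizes.

The BM model implies cov(species i, j) = shared root-to-MRCA depth, so the
tree enters as an n x n covariance C_tree.  A Cholesky transform maps GLS to
OLS: with C_tree = L L', premultiplying Y and X by L^-1 whitens the
phylogenetic correlation, and all sums of squares are computed in that
transformed (GLS-metric) space.  Significance comes from permuting reduced-
model residuals in the transformed space and recomputing F, the standard
residual-randomization scheme for phylogenetic linear models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io import PhyloTree

__all__ = [
    "PGLSFit",
    "PermutationResult",
    "pgls_fit",
    "rrpp_significance",
    "allometric_vector",
    "slope_heterogeneity_test",
    "pgls_scalar",
    "design_matrix",
]


@dataclass
class PGLSFit:
    """A fitted (multivariate) phylogenetic regression."""

    coefficients: np.ndarray       # (q, k)
    fitted: np.ndarray             # (n, k) on the original scale
    residuals: np.ndarray          # (n, k)
    R2: float
    F: float
    SS_model: float
    SS_resid: float
    SS_total: float
    df_model: int
    df_resid: int
    design_labels: list[str]
    # whitened-space quantities kept for permutation procedures
    Xw: np.ndarray = field(repr=False, default=None)
    Yw: np.ndarray = field(repr=False, default=None)
    L: np.ndarray = field(repr=False, default=None)


@dataclass
class PermutationResult:
    """P-value and standardized effect size from a permutation null.

    P uses the +1 convention (the observed statistic is a member of its own
    null), so the smallest attainable P is 1/(n_perm+1).
    """

    P: float
    Z: float
    n_perm: int
    observed: float
    null_stats: np.ndarray
    seed: int


def design_matrix(
    predictors: dict[str, np.ndarray], interactions: list[tuple[str, str]] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix with intercept from named columns.

    Categorical (non-numeric) predictors are dummy-coded dropping the first
    level; interactions are products of the expanded columns.
    """
    cols: list[np.ndarray] = [np.ones(len(next(iter(predictors.values()))))]
    labels = ["intercept"]
    expanded: dict[str, list[tuple[str, np.ndarray]]] = {}
    for name, values in predictors.items():
        values = np.asarray(values)
        if values.dtype.kind in "fiu":
            expanded[name] = [(name, values.astype(float))]
        else:
            levels = list(dict.fromkeys(values.tolist()))
            expanded[name] = [
                (f"{name}[{lev}]", (values == lev).astype(float)) for lev in levels[1:]
            ]
        for lab, col in expanded[name]:
            cols.append(col)
            labels.append(lab)
    for a, b in interactions or []:
        for lab_a, col_a in expanded[a]:
            for lab_b, col_b in expanded[b]:
                cols.append(col_a * col_b)
                labels.append(f"{lab_a}:{lab_b}")
    return np.column_stack(cols), labels


def _whitener(tree_or_C, n: int) -> np.ndarray:
    """Cholesky factor L of the BM covariance (C = L L')."""
    if isinstance(tree_or_C, PhyloTree):
        C = tree_or_C.vcv()
    else:
        C = np.asarray(tree_or_C, dtype=float)
    if C.shape != (n, n):
        raise ValueError(f"covariance is {C.shape}, expected ({n}, {n})")
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("BM covariance is not positive definite") from exc


def _gls_solve(Xw: np.ndarray, Yw: np.ndarray, labels: list[str]) -> np.ndarray:
    q = Xw.shape[1]
    rank = np.linalg.matrix_rank(Xw)
    if rank < q:
        # name the offending columns for the error message
        _, R = np.linalg.qr(Xw)
        diag = np.abs(np.diag(R))
        bad = [labels[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    B, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    return B


def pgls_fit(
    Y: np.ndarray,
    X: np.ndarray,
    tree: PhyloTree | np.ndarray,
    design_labels: list[str] | None = None,
) -> PGLSFit:
    """GLS fit of an n x k response on a design matrix under BM covariance.

    Row order of Y and X must match the tree's tip order (``tree.taxa``).
    X must include an intercept column; sums of squares are computed about
    the GLS (phylogenetic) mean, in the whitened space.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = Y.shape
    labels = design_labels or [f"x{i}" for i in range(X.shape[1])]
    L = _whitener(tree, n)
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    Yw = scipy.linalg.solve_triangular(L, Y, lower=True)
    B = _gls_solve(Xw, Yw, labels)

    ones_w = scipy.linalg.solve_triangular(L, np.ones((n, 1)), lower=True)
    a, *_ = np.linalg.lstsq(ones_w, Yw, rcond=None)  # GLS mean
    fitted_w = Xw @ B
    resid_w = Yw - fitted_w
    SS_resid = float((resid_w**2).sum())
    SS_total = float(((Yw - ones_w @ a) ** 2).sum())
    SS_model = SS_total - SS_resid
    q = np.linalg.matrix_rank(Xw)
    df_model = max(q - 1, 1)
    df_resid = n - q
    F = (SS_model / df_model) / (SS_resid / df_resid) if SS_resid > 0 else np.inf
    R2 = SS_model / SS_total if SS_total > 0 else 0.0
    return PGLSFit(
        coefficients=B,
        fitted=X @ B,
        residuals=Y - X @ B,
        R2=R2,
        F=F,
        SS_model=SS_model,
        SS_resid=SS_resid,
        SS_total=SS_total,
        df_model=df_model,
        df_resid=df_resid,
        design_labels=labels,
        Xw=Xw,
        Yw=Yw,
        L=L,
    )


def _f_stat(Xw_full, Xw_red, Yw) -> float:
    """F comparing nested designs in the whitened space."""
    B_f, *_ = np.linalg.lstsq(Xw_full, Yw, rcond=None)
    B_r, *_ = np.linalg.lstsq(Xw_red, Yw, rcond=None)
    ss_f = float(((Yw - Xw_full @ B_f) ** 2).sum())
    ss_r = float(((Yw - Xw_red @ B_r) ** 2).sum())
    df_diff = np.linalg.matrix_rank(Xw_full) - np.linalg.matrix_rank(Xw_red)
    df_resid = Yw.shape[0] - np.linalg.matrix_rank(Xw_full)
    if ss_f <= 0:
        return np.inf
    return ((ss_r - ss_f) / df_diff) / (ss_f / df_resid)


def _perm_pvalue(observed: float, null: np.ndarray) -> float:
    return (1 + int(np.sum(null >= observed))) / (len(null) + 1)


def _effect_size(observed: float, null: np.ndarray, log_transform: bool) -> float:
    vals = np.append(null, observed)
    if log_transform:
        vals = np.log(np.maximum(vals, np.finfo(float).tiny))
        obs = vals[-1]
    else:
        obs = observed
    mu, sd = vals[:-1].mean(), vals[:-1].std(ddof=1)
    return float((obs - mu) / sd) if sd > 0 else np.inf


def rrpp_significance(
    fit: PGLSFit,
    n_perm: int = 999,
    seed: int = 0,
    reduced_X: np.ndarray | None = None,
    log_f: bool = False,
) -> PermutationResult:
    """Residual-randomization P and effect size for a fitted PGLS model.

    Whitened residuals of the reduced model (default: intercept only) are
    permuted, added back to the reduced fitted values, and F is recomputed
    each round.  Z is the standardized position of observed F in its null
    (optionally on the log-F scale).
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; P-value resolution is coarse")
    rng = np.random.default_rng(seed)
    Yw, Xw = fit.Yw, fit.Xw
    n = Yw.shape[0]
    if reduced_X is None:
        Xw_red = scipy.linalg.solve_triangular(fit.L, np.ones((n, 1)), lower=True)
    else:
        Xw_red = scipy.linalg.solve_triangular(fit.L, reduced_X, lower=True)
    B_r, *_ = np.linalg.lstsq(Xw_red, Yw, rcond=None)
    fitted_r = Xw_red @ B_r
    resid_r = Yw - fitted_r
    obs = _f_stat(Xw, Xw_red, Yw)
    null = np.empty(n_perm)
    for b in range(n_perm):
        Yb = fitted_r + resid_r[rng.permutation(n)]
        null[b] = _f_stat(Xw, Xw_red, Yb)
    return PermutationResult(
        P=_perm_pvalue(obs, null),
        Z=_effect_size(obs, null, log_f),
        n_perm=n_perm,
        observed=obs,
        null_stats=null,
        seed=seed,
    )


def allometric_vector(fit: PGLSFit, predictor: str) -> np.ndarray:
    """Unit-length vector of allometric coefficients (the CREA axis).

    The row of the coefficient matrix belonging to ``predictor`` (log
    centroid size), normalized to unit length; its sign is the direction of
    shape change with *increasing* size.
    """
    try:
        row = fit.design_labels.index(predictor)
    except ValueError as exc:
        raise KeyError(
            f"{predictor!r} not in design {fit.design_labels}"
        ) from exc
    v = fit.coefficients[row].astype(float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"zero-length coefficient row for {predictor!r}")
    return v / norm


def slope_heterogeneity_test(
    Y: np.ndarray,
    log_cs: np.ndarray,
    groups: np.ndarray,
    tree: PhyloTree | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Test whether allometric slopes differ between groups (subfamilies).

    Compares the full model (size x group interaction) against the
    common-slope model (size + group) by F on the GLS sums of squares, with
    significance from permuting the common-slope model's whitened residuals.
    Groups with fewer than 3 members are excluded with a warning.
    """
    groups = np.asarray(groups)
    log_cs = np.asarray(log_cs, dtype=float)
    Y = np.asarray(Y, dtype=float)
    levels, counts = np.unique(groups, return_counts=True)
    small = levels[counts < 3]
    if small.size:
        warnings.warn(f"excluding groups with <3 members: {small.tolist()}")
        keep = ~np.isin(groups, small)
        if isinstance(tree, PhyloTree):
            tree = tree.prune_to(np.asarray(tree.taxa)[keep])
        else:
            tree = tree[np.ix_(keep, keep)]
        Y, log_cs, groups = Y[keep], log_cs[keep], groups[keep]
        levels = levels[counts >= 3]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups of >=3 members to test slopes")
    X_full, labels = design_matrix(
        {"log_cs": log_cs, "group": groups}, interactions=[("log_cs", "group")]
    )
    X_red, _ = design_matrix({"log_cs": log_cs, "group": groups})
    n = len(log_cs)
    L = _whitener(tree, n)
    Xw_full = scipy.linalg.solve_triangular(L, X_full, lower=True)
    Xw_red = scipy.linalg.solve_triangular(L, X_red, lower=True)
    Yw = scipy.linalg.solve_triangular(L, np.atleast_2d(Y.T).T, lower=True)
    obs = _f_stat(Xw_full, Xw_red, Yw)
    B_r, *_ = np.linalg.lstsq(Xw_red, Yw, rcond=None)
    fitted_r, resid_r = Xw_red @ B_r, Yw - Xw_red @ B_r
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        Yb = fitted_r + resid_r[rng.permutation(n)]
        null[b] = _f_stat(Xw_full, Xw_red, Yb)
    return PermutationResult(
        P=_perm_pvalue(obs, null),
        Z=_effect_size(obs, null, False),
        n_perm=n_perm,
        observed=obs,
        null_stats=null,
        seed=seed,
    )


def pgls_scalar(
    y: np.ndarray,
    x: np.ndarray,
    tree: PhyloTree | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[PGLSFit, PermutationResult]:
    """Scalar-on-scalar phylogenetic regression with RRPP significance."""
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    fit = pgls_fit(np.asarray(y, dtype=float)[:, None], X, tree,
                   design_labels=["intercept", "x"])
    perm = rrpp_significance(fit, n_perm=n_perm, seed=seed)
    return fit, perm
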