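"""Line-of-least-resistance statistics.

The central quantity is the projected variance V_proj = x' P x: the variance
of a species' phenotypic covariance matrix P in a unit direction x (the
"evolvability" of P along x).  With x the evolutionary allometric (CREA)
vector, V_proj measures how strongly within-species variation is biased
toward allometry.  Companion statistics: a random-vector null for V_proj,
the relative eigenvalue variance Vrel and its effect size Z_rel (morphological
integration), divergence magnitude and direction from an inferred ancestor,
vector angles with hyperdimensional random-angle nulls, and the
browser-grazer (percent-grass) axis with its quadratic trend surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .io import PhyloTree
from .pgls import PGLSFit, pgls_fit, rrpp_significance, PermutationResult

__all__ = [
    "PMatrix",
    "LLRRecord",
    "AngleNull",
    "p_matrix",
    "projected_variance",
    "random_vector_null",
    "integration_effect_size",
    "divergence_magnitude",
    "divergence_vector",
    "vector_angle",
    "random_angle_null",
    "angle_significance",
    "ks_angles_vs_null",
    "ecology_axis",
    "trend_surface",
    "TrendSurface",
]


@dataclass
class PMatrix:
    """One species' phenotypic variance-covariance matrix in tangent space."""

    species_id: str
    P: np.ndarray   # (k, k) symmetric PSD
    n: int          # specimens

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("P must be symmetric")
        self.P = (P + P.T) / 2

    @property
    def trace(self) -> float:
        return float(np.trace(self.P))

    @property
    def k(self) -> int:
        return self.P.shape[0]


@dataclass
class LLRRecord:
    """Per-species bundle of line-of-least-resistance statistics."""

    species_id: str
    Vproj_crea: float
    Vproj_crea_frac: float
    Vproj_random_mean: float
    Vproj_divergence: float
    Vrel: float
    Zrel: float
    divergence_D: float
    angle_deg: float
    centroid_size: float


def p_matrix(tangent_vectors: np.ndarray, species_id: str = "") -> PMatrix:
    """Sample covariance (divisor n-1) of one species' specimen tangent
    coordinates."""
    X = np.asarray(tangent_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 specimens to estimate P")
    Xc = X - X.mean(axis=0)
    P = Xc.T @ Xc / (X.shape[0] - 1)
    return PMatrix(species_id=species_id, P=P, n=X.shape[0])


def projected_variance(P: PMatrix | np.ndarray, x: np.ndarray,
                       normalize: bool = False) -> float:
    """V_proj = x' P x for a unit direction x.

    With ``normalize`` the raw value is divided by trace(P), giving the
    proportion of the species' total shape variance lying along x.
    """
    M = P.P if isinstance(P, PMatrix) else np.asarray(P, dtype=float)
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("direction vector is zero")
    if abs(norm - 1) > 1e-8:
        warnings.warn("direction not unit length; renormalizing")
        x = x / norm
    v = float(x @ M @ x)
    if normalize:
        tr = float(np.trace(M))
        return v / tr if tr > 0 else 0.0
    return v


def random_unit_vectors(k: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n vectors uniform on the unit (k-1)-sphere (normalized Gaussians)."""
    V = rng.standard_normal((n, k))
    return V / np.linalg.norm(V, axis=1, keepdims=True)


def random_vector_null(
    P: PMatrix | np.ndarray,
    n_vectors: int = 499,
    seed: int = 0,
    normalize: bool = False,
) -> tuple[float, np.ndarray]:
    """V_proj of ``n_vectors`` random unit directions (and their mean).

    The analytic expectation of x'Px over uniform unit x is trace(P)/k, the
    value an unremarkable direction attains on average.
    """
    M = P.P if isinstance(P, PMatrix) else np.asarray(P, dtype=float)
    rng = np.random.default_rng(seed)
    V = random_unit_vectors(M.shape[0], n_vectors, rng)
    vals = np.einsum("ij,jk,ik->i", V, M, V)
    if normalize:
        tr = float(np.trace(M))
        vals = vals / tr if tr > 0 else vals * 0.0
    return float(vals.mean()), vals


def relative_eigenvalue_variance(P: PMatrix | np.ndarray) -> float:
    """Vrel: eigenvalue dispersion of P scaled to [0, 1].

    Variance of the eigenvalues divided by its maximum attainable value at
    the same trace and dimension (attained by a rank-1 matrix); 0 for an
    isotropic matrix, 1 for rank 1.  For two traits of equal variance and
    correlation r, Vrel = r^2.
    """
    M = P.P if isinstance(P, PMatrix) else np.asarray(P, dtype=float)
    d = M.shape[0]
    if d < 2:
        raise ValueError("Vrel undefined for k=1")
    lam = np.linalg.eigvalsh(M)
    T = lam.sum()
    if T <= 0:
        return 0.0
    var = np.mean((lam - lam.mean()) ** 2)
    var_max = T**2 * (d - 1) / d**2
    return float(var / var_max)


def integration_effect_size(
    P: PMatrix, method: str = "fisher"
) -> tuple[float, float]:
    """(Vrel, Z_rel): integration magnitude and its standardized effect size.

    Z_rel is the Fisher z-transform of sqrt(Vrel) scaled by sqrt(n-3) — the
    reciprocal standard error of a Fisher-z correlation at the species'
    sample size — so equally eccentric P-matrices estimated from more
    specimens yield larger effect sizes.  ``method="raw"`` returns
    atanh(sqrt(Vrel)) without the sample-size scaling.
    """
    vrel = relative_eigenvalue_variance(P)
    r = min(np.sqrt(vrel), 1 - 1e-15)
    z = np.arctanh(r)
    if method == "fisher" and P.n > 3:
        z = z * np.sqrt(P.n - 3)
    return float(vrel), float(z)


def divergence_magnitude(species_scores: np.ndarray,
                         ancestor_scores: np.ndarray) -> float:
    """Euclidean distance between a species' ordination scores and its
    subfamily ancestor's scores."""
    a = np.asarray(species_scores, dtype=float)
    b = np.asarray(ancestor_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"axis mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def divergence_vector(
    species_tangent: np.ndarray, ancestor_tangent: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None]:
    """Direction of divergence: (species - ancestor), raw and unit-normalized.

    The unit copy is None (flagged undefined) when species and ancestor
    coincide.
    """
    a = np.asarray(species_tangent, dtype=float)
    b = np.asarray(ancestor_tangent, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"basis mismatch: {a.shape} vs {b.shape}")
    d = a - b
    norm = np.linalg.norm(d)
    return d, (d / norm if norm > 0 else None)


def vector_angle(a: np.ndarray, b: np.ndarray, fold: bool = False) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    ``fold=True`` treats directions as axes and maps to [0, 90] via
    min(theta, 180 - theta).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for zero vector")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos)))
    return min(theta, 180.0 - theta) if fold else theta


@dataclass
class AngleNull:
    """Null distribution of angles between random unit-vector pairs in k-D.

    In high dimensions random vectors are nearly orthogonal: the null is
    centered at 90 degrees with standard deviation shrinking as k grows
    (~ 1/sqrt(k) radians); at k=2 it is uniform on [0, 180].
    """

    k: int
    samples: np.ndarray = field(repr=False)
    n: int = 0
    seed: int = 0

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1))


def random_angle_null(k: int, n: int = 10000, seed: int = 0) -> AngleNull:
    """Angles between n independent pairs of uniform unit vectors in k-D."""
    if k < 2:
        raise ValueError("need k >= 2")
    rng = np.random.default_rng(seed)
    A = random_unit_vectors(k, n, rng)
    B = random_unit_vectors(k, n, rng)
    cos = np.clip(np.einsum("ij,ij->i", A, B), -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    return AngleNull(k=k, samples=ang, n=n, seed=seed)


def angle_significance(
    a: np.ndarray,
    b: np.ndarray,
    n_random: int = 10000,
    seed: int = 0,
    null: AngleNull | None = None,
) -> tuple[float, float]:
    """Observed angle between a and b, and the one-sided probability that two
    random k-dimensional vectors would be at least as aligned (angle as small
    or smaller), +1 convention."""
    theta = vector_angle(a, b)
    if null is None:
        null = random_angle_null(len(np.asarray(a).ravel()), n=n_random, seed=seed)
    P = (1 + int(np.sum(null.samples <= theta))) / (null.n + 1)
    return theta, P


def ks_angles_vs_null(observed_angles: np.ndarray, null: AngleNull) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test of observed divergence
    angles against the random-angle null.  Returns (D, P)."""
    obs = np.asarray(observed_angles, dtype=float)
    if obs.size < 5:
        raise ValueError("need at least 5 observed angles")
    res = ks_2samp(obs, null.samples, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ecology_axis(
    Y: np.ndarray,
    percent_grass: np.ndarray,
    tree: PhyloTree | np.ndarray,
    taxa: list[str] | None = None,
) -> tuple[np.ndarray, PGLSFit]:
    """Axis of shape variation along the browser-grazer continuum.

    PGLS of shape on percent grass in diet over the species with diet data;
    the coefficient row is unit-normalized like the allometric vector.
    Species with missing diet values are excluded (tree re-pruned).
    """
    Y = np.asarray(Y, dtype=float)
    g = np.asarray(percent_grass, dtype=float)
    have = np.isfinite(g)
    if have.sum() < 10:
        warnings.warn(f"only {int(have.sum())} species with diet data")
    if have.sum() < 3:
        raise ValueError("too few species with diet data")
    if np.ptp(g[have]) == 0:
        raise ValueError("percent_grass is constant; axis undefined")
    if isinstance(tree, PhyloTree):
        order = taxa if taxa is not None else tree.taxa
        keep = [t for t, h in zip(order, have) if h]
        C = tree.prune_to(keep).vcv(order=keep)
    else:
        C = np.asarray(tree, dtype=float)[np.ix_(have, have)]
    Ysub, gsub = Y[have], g[have]
    X = np.column_stack([np.ones(have.sum()), gsub])
    fit = pgls_fit(Ysub, X, C, design_labels=["intercept", "percent_grass"])
    v = fit.coefficients[1]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate diet axis (zero coefficients)")
    return v / norm, fit


@dataclass
class TrendSurface:
    """Second-degree polynomial surface of a response over two ordination
    axes, basis {1, u, v, u^2, uv, v^2}."""

    coefficients: np.ndarray
    R2: float
    P: float
    degree: int = 2

    def __call__(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        B = _poly_basis(u.ravel(), v.ravel(), self.degree)
        return (B @ self.coefficients).reshape(u.shape)


def _poly_basis(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(u)]
    for d in range(1, degree + 1):
        for j in range(d + 1):
            cols.append(u ** (d - j) * v**j)
    return np.column_stack(cols)


def trend_surface(
    pc_scores: np.ndarray,
    response: np.ndarray,
    degree: int = 2,
    n_perm: int = 999,
    seed: int = 0,
) -> TrendSurface:
    """Least-squares polynomial surface with a permutation P-value.

    Significance permutes response rows against the score basis and compares
    R^2 (equivalent to F for a fixed design), +1 convention.
    """
    S = np.asarray(pc_scores, dtype=float)
    y = np.asarray(response, dtype=float)
    if S.shape[0] < 10:
        raise ValueError("need at least 10 observations for a surface fit")
    B = _poly_basis(S[:, 0], S[:, 1], degree)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("rank-deficient polynomial basis (degenerate scores)")

    def r2_of(yy: np.ndarray) -> tuple[np.ndarray, float]:
        coef, *_ = np.linalg.lstsq(B, yy, rcond=None)
        resid = yy - B @ coef
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        return coef, 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0

    coef, r2 = r2_of(y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        _, null[b] = r2_of(y[rng.permutation(len(y))])
    P = (1 + int(np.sum(null >= r2))) / (n_perm + 1)
    return TrendSurface(coefficients=coef, R2=r2, P=P, degree=degree)
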