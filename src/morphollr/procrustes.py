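"""Generalized Procrustes analysis and tangent-space projection.

GPA separates shape from size, position and orientation: every configuration
is translated to a common centroid, scaled to unit centroid size, and rotated
(rotations only, no reflections — crania are chiral) onto an iteratively
updated consensus.  Shapes then live on a curved manifold; statistics are done
in the linear tangent space at the consensus, which for p 3-D landmarks has
3p - 7 dimensions (3 translations, 3 rotations and 1 scale removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import LandmarkConfiguration

__all__ = [
    "centroid_size",
    "gpa",
    "GPAResult",
    "tangent_project",
    "tangent_basis",
    "species_means",
    "procrustes_distance",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid.

    The standard geometric-morphometric size proxy.  Zero for a degenerate
    configuration with all landmarks coincident.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||A @ R - B||_F."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d]) if A.shape[1] == 3 else np.diag([1.0, d])
    return U @ D @ Vt


@dataclass
class GPAResult:
    """Output of generalized Procrustes superimposition.

    aligned configurations are centered at the origin with unit centroid
    size; ``tangent`` holds coordinates in the (3p-7)-dimensional tangent
    space at the consensus, with the orthonormal basis stored so specimens
    from outside the original sample can be projected consistently.
    """

    aligned: np.ndarray          # (n, p, 3)
    consensus: np.ndarray        # (p, 3), unit centroid size
    centroid_size: np.ndarray    # (n,)
    log_cs: np.ndarray           # (n,)
    tangent: np.ndarray          # (n, k)
    basis: np.ndarray            # (3p, k) orthonormal tangent basis
    specimen_ids: list[str]
    species_ids: list[str]
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.tangent.shape[1]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Superimpose an external p x 3 configuration on the consensus and
        return its tangent coordinates in this result's basis."""
        c = np.asarray(coords, dtype=float)
        c = c - c.mean(axis=0)
        cs = np.sqrt((c**2).sum())
        if cs == 0:
            raise ValueError("degenerate configuration (zero centroid size)")
        c = c / cs
        R = _optimal_rotation(c, self.consensus)
        flat = (c @ R).ravel() - self.consensus.ravel()
        return flat @ self.basis


def _raw_config(i: int, coords: np.ndarray) -> LandmarkConfiguration:
    c = LandmarkConfiguration.__new__(LandmarkConfiguration)
    c.specimen_id = f"cfg{i}"
    c.species_id = f"cfg{i}"
    c.coords = np.asarray(coords, dtype=float)
    if c.coords.ndim != 2 or c.coords.shape[1] != 3 or c.coords.shape[0] < 3:
        raise ValueError("raw configuration must be p x 3 with p >= 3")
    return c


def _normalize(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs == 0:
        raise ValueError("degenerate configuration (zero centroid size)")
    return centered / cs, cs


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes superimposition of a landmark sample.

    Iterates rotate-to-consensus / update-consensus until the change in
    summed squared Procrustes distance to the consensus falls below ``tol``.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    if isinstance(configs[0], np.ndarray):
        # raw arrays allowed (e.g. triangles below the dataset minimum of 4)
        configs = [_raw_config(i, a) for i, a in enumerate(configs)]
    p = configs[0].n_landmarks
    n = len(configs)
    X = np.empty((n, p, 3))
    cs = np.empty(n)
    for i, c in enumerate(configs):
        X[i], cs[i] = _normalize(c.coords)

    consensus, _ = _normalize(X[0])
    prev_ss = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        consensus, _ = _normalize(X.mean(axis=0))
        ss = float(((X - consensus) ** 2).sum())
        if abs(prev_ss - ss) < tol:
            converged = True
            break
        prev_ss = ss
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")

    basis = tangent_basis(consensus)
    tangent = (X.reshape(n, -1) - consensus.ravel()) @ basis
    return GPAResult(
        aligned=X,
        consensus=consensus,
        centroid_size=cs,
        log_cs=np.log(cs),
        tangent=tangent,
        basis=basis,
        specimen_ids=[c.specimen_id for c in configs],
        species_ids=[c.species_id for c in configs],
        iterations=it,
        converged=converged,
    )


def tangent_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3p x k) of the shape tangent space at ``consensus``.

    The 3p-dimensional space of flattened configurations loses 7 degrees of
    freedom: 3 rigid translations, 1 uniform scaling (the direction of the
    consensus itself), and 3 infinitesimal rotations (skew generators applied
    to the consensus).  The basis spans the orthogonal complement of those
    seven directions, so k = 3p - 7 for non-degenerate consensus shapes.
    """
    consensus = np.asarray(consensus, dtype=float)
    p = consensus.shape[0]
    degen = []
    for axis in range(3):
        t = np.zeros((p, 3))
        t[:, axis] = 1.0
        degen.append(t.ravel())
    degen.append(consensus.ravel())  # scale direction
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    ]
    for J in gens:
        degen.append((consensus @ J.T).ravel())
    N = np.column_stack(degen)
    # drop linearly dependent generators (flat/collinear consensus shapes)
    Q, R = np.linalg.qr(N)
    keep = np.abs(np.diag(R)) > 1e-10 * np.abs(np.diag(R)).max()
    return scipy.linalg.null_space(Q[:, keep].T)


def tangent_project(result: GPAResult, mode: str = "orthogonal") -> np.ndarray:
    """Tangent coordinates of the superimposed sample.

    mode="orthogonal" (default): orthogonal projection at the consensus onto
    the (3p-7)-dimensional tangent basis.  mode="none": mean-centered
    flattened coordinates without removing the degenerate dimensions.
    """
    n = result.n
    flat = result.aligned.reshape(n, -1)
    if mode == "orthogonal":
        return (flat - result.consensus.ravel()) @ result.basis
    if mode == "none":
        return flat - flat.mean(axis=0)
    raise ValueError(f"unknown tangent mode {mode!r}")


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations: the Frobenius
    distance after centering, unit-scaling, and optimal rotation."""
    A, _ = _normalize(np.asarray(a, dtype=float))
    B, _ = _normalize(np.asarray(b, dtype=float))
    A = A @ _optimal_rotation(A, B)
    return float(np.sqrt(((A - B) ** 2).sum()))


def species_means(
    result: GPAResult, species_ids: list[str] | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-species mean tangent coordinates and mean centroid sizes.

    Centroid size is averaged on the raw scale and logged afterwards.
    Returns (species labels, m x k mean tangent matrix, m log mean sizes).
    """
    labels = species_ids if species_ids is not None else result.species_ids
    if len(labels) != result.n:
        raise ValueError("one species label per specimen required")
    order = list(dict.fromkeys(labels))
    lab_arr = np.asarray(labels)
    means = np.empty((len(order), result.k))
    log_cs = np.empty(len(order))
    for i, s in enumerate(order):
        mask = lab_arr == s
        means[i] = result.tangent[mask].mean(axis=0)
        log_cs[i] = np.log(result.centroid_size[mask].mean())
    return order, means, log_cs
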