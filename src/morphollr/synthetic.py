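"""Synthetic study generator with full ground truth.

Emulates the statistical structure the analysis assumes: species-mean shapes
evolving on a pure-birth phylogeny under multivariate Brownian motion with a
rate matrix elongated along a designated allometric ("face elongation")
direction; log centroid size tied to position along that direction; percent
grass in diet a logistic readout of size; and intraspecific specimen samples
drawn from per-species P-matrices of controllable eccentricity and
controllable alignment with the allometric direction.  Every stochastic layer
is seeded and its generating parameters are kept in a :class:`SyntheticTruth`
for recovery tests.

Default scale mirrors the empirical design the pipeline targets: 130 species,
49 of them with at least 27 specimens, p = 28 landmarks (tangent dimension
3p - 7 = 77).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import LandmarkConfiguration, PhyloTree, write_landmarks
from .procrustes import tangent_basis

__all__ = [
    "ShapeSystem",
    "SyntheticTruth",
    "simulate_tree",
    "make_shape_system",
    "make_truth",
    "simulate_species",
    "simulate_populations",
    "clades_at_depth",
    "synthetic_taxon_table",
    "generate_study",
]


def simulate_tree(n_tips: int, seed: int = 0, min_tip_split: float = 0.02) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips``, rescaled to unit depth.

    Forward simulation: starting from two lineages, wait an Exp(rate x m)
    time, split a uniformly chosen lineage, repeat until n lineages exist,
    then extend all pendant branches by a final waiting time.  The final
    extension is floored at ``min_tip_split`` of the tree depth so the most
    recent divergence between sampled tips stays bounded away from zero —
    the situation of a species-level taxon sample, where subspecies-young
    splits are not in the tree (set 0 for a raw Yule tree).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []  # (node, birth time)
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    ext = rng.exponential(1.0 / len(active))
    t += max(ext, min_tip_split * t)
    taxon_namespace = dendropy.TaxonNamespace()
    for j, (node, birth) in enumerate(active):
        node.edge.length = t - birth
        node.taxon = taxon_namespace.new_taxon(label=f"sp{j:03d}")
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    # rescale to unit depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    return PhyloTree(tree)


@dataclass
class ShapeSystem:
    """A reference mean shape with its tangent basis and a designated
    allometric deformation direction."""

    mean_shape: np.ndarray        # (p, 3), centered, unit centroid size
    basis: np.ndarray             # (3p, k) orthonormal tangent basis
    crea_index: int               # basis column designated "face elongation"

    @property
    def p(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    @property
    def crea_direction(self) -> np.ndarray:
        """Unit k-vector of the allometric direction in tangent coordinates."""
        e = np.zeros(self.k)
        e[self.crea_index] = 1.0
        return e

    def to_landmarks(self, tangent: np.ndarray) -> np.ndarray:
        """Map tangent coordinates to a p x 3 landmark configuration."""
        flat = self.mean_shape.ravel() + self.basis @ np.asarray(tangent, dtype=float)
        return flat.reshape(self.p, 3)


def make_shape_system(p_landmarks: int = 28, seed: int = 0) -> ShapeSystem:
    """Reproducible 3-D reference shape and tangent basis.

    The mean shape is a fixed random scatter (centered, unit centroid size);
    the basis spans the 3p - 7 dimensional tangent space at it.  Basis column
    0 is designated the allometric direction.
    """
    if p_landmarks < 8:
        raise ValueError("need at least 8 landmarks")
    rng = np.random.default_rng(seed)
    shape = rng.standard_normal((p_landmarks, 3))
    shape -= shape.mean(axis=0)
    shape /= np.sqrt((shape**2).sum())
    basis = tangent_basis(shape)
    return ShapeSystem(mean_shape=shape, basis=basis, crea_index=0)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study."""

    tree: PhyloTree
    shape_system: ShapeSystem
    crea_direction: np.ndarray            # (k,), unit
    allometric_slope: float               # shape displacement per unit log CS
    rate_matrix_true: np.ndarray          # (k, k)
    rate_eccentricity: float              # fraction of total rate along CREA
    p_true: dict[str, np.ndarray]         # species -> (k, k)
    alignment_true: dict[str, float]      # angle (deg) of P's leading axis to CREA
    eccentricity_true: dict[str, float]   # lambda_1 / trace of P
    diet_coupling: float
    llr_coupling: float
    size_noise_sd: float
    seed: int
    intraspecific_species: list[str] = field(default_factory=list)


def _elongated_cov(
    k: int, total: float, leading_fraction: float, v1: np.ndarray
) -> np.ndarray:
    """PSD matrix with trace ``total``, fraction ``leading_fraction`` of it on
    axis v1 and the rest isotropic in the complement."""
    v1 = v1 / np.linalg.norm(v1)
    P1 = np.outer(v1, v1)
    lam_rest = total * (1 - leading_fraction) / (k - 1)
    return total * leading_fraction * P1 + lam_rest * (np.eye(k) - P1)


def make_truth(
    tree: PhyloTree,
    shape_system: ShapeSystem,
    n_intraspecific: int = 49,
    rate_total: float = 0.04,
    rate_eccentricity: float = 0.35,
    allometric_slope: float = 0.15,
    p_trace: float = 0.01,
    p_eccentricity: float = 0.2,
    alignment_range_deg: tuple[float, float] = (20.0, 70.0),
    diet_coupling: float = 2.0,
    llr_coupling: float = 0.0,
    size_noise_sd: float = 0.15,
    seed: int = 0,
) -> SyntheticTruth:
    """Build the generating parameters of a synthetic study.

    rate_total: trace of the BM rate matrix (squared tangent units per unit
    tree depth).  rate_eccentricity: fraction of the total rate concentrated
    along the allometric direction (default 0.35, so the allometric axis
    dominates the interspecific ordination the way it does in ruminant
    crania; 1/k would be isotropic).  p_trace / p_eccentricity: trace and leading-eigenvalue
    fraction of each species' P.  alignment_range_deg: per-species angles of
    P's leading axis to CREA are drawn uniformly in this range.  llr_coupling
    couples divergence to alignment: species whose P is aligned with CREA
    receive extra displacement along it (0 = pure BM divergence).
    """
    rng = np.random.default_rng(seed)
    k = shape_system.k
    u = shape_system.crea_direction
    C_true = _elongated_cov(k, rate_total, rate_eccentricity, u)
    species = tree.taxa
    intra = sorted(rng.choice(species, size=min(n_intraspecific, len(species)),
                              replace=False).tolist())
    p_true, align, ecc = {}, {}, {}
    for s in species:
        alpha = float(rng.uniform(*alignment_range_deg))
        w = rng.standard_normal(k)
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        v1 = np.cos(np.radians(alpha)) * u + np.sin(np.radians(alpha)) * w
        p_true[s] = _elongated_cov(k, p_trace, p_eccentricity, v1)
        align[s] = alpha
        ecc[s] = p_eccentricity
    return SyntheticTruth(
        tree=tree,
        shape_system=shape_system,
        crea_direction=u,
        allometric_slope=allometric_slope,
        rate_matrix_true=C_true,
        rate_eccentricity=rate_eccentricity,
        p_true=p_true,
        alignment_true=align,
        eccentricity_true=ecc,
        diet_coupling=diet_coupling,
        llr_coupling=llr_coupling,
        size_noise_sd=size_noise_sd,
        seed=seed,
        intraspecific_species=intra,
    )


def simulate_species(
    tree: PhyloTree, truth: SyntheticTruth, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Species means under multivariate BM, with sizes and diets.

    Returns (mean tangent vectors n x k, log centroid sizes, percent grass).
    Log size is the species' projection on the allometric direction divided
    by the allometric slope, plus an independent BM component (rate
    ``size_noise_sd``^2), so a shape-on-size regression recovers the
    direction with slope ~ ``allometric_slope``.
    Percent grass is a logistic readout of standardized size with unit
    Gaussian noise scaled against ``diet_coupling`` (coupling 0 = diet
    independent of size).
    """
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    k = truth.shape_system.k
    Ct = tree.vcv()
    Lt = np.linalg.cholesky(Ct)
    Lc = _psd_factor(truth.rate_matrix_true)
    means = Lt @ rng.standard_normal((n, k)) @ Lc.T
    u = truth.crea_direction
    if truth.llr_coupling > 0:
        # "selection" along the LLR: species with P aligned to CREA get extra
        # displacement along it, independent across species
        for i, s in enumerate(tree.taxa):
            a = np.cos(np.radians(truth.alignment_true[s])) ** 2
            means[i] += (
                truth.llr_coupling * a * rng.standard_normal()
                * np.sqrt(np.trace(truth.rate_matrix_true)) * u
            )
    proj = means @ u
    # non-allometric size evolution is itself Brownian on the tree
    size_bm = truth.size_noise_sd * (Lt @ rng.standard_normal(n))
    log_cs = proj / truth.allometric_slope + size_bm
    z = (log_cs - log_cs.mean()) / max(log_cs.std(), 1e-12)
    grass = 100.0 / (1.0 + np.exp(-(truth.diet_coupling * z + rng.standard_normal(n))))
    return means, log_cs, grass


def _psd_factor(M: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(np.asarray(M, dtype=float))
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_populations(
    species_means: np.ndarray,
    log_cs: np.ndarray,
    truth: SyntheticTruth,
    n_specimens: dict[str, int] | int,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> list[LandmarkConfiguration]:
    """Specimen landmark configurations for each species.

    Each specimen is the species mean plus a draw from the species' true P
    (in tangent space), mapped back to landmarks through the deformation
    basis, plus isotropic digitizing noise (default sd = 1% of the reference
    centroid size), then scaled by the species' centroid size and hit with an
    arbitrary rigid motion so superimposition has real work to do.
    """
    rng = np.random.default_rng(seed)
    sysm = truth.shape_system
    configs: list[LandmarkConfiguration] = []
    taxa = truth.tree.taxa
    for i, s in enumerate(taxa):
        n_i = n_specimens if isinstance(n_specimens, int) else n_specimens.get(s, 0)
        if n_i <= 0:
            continue
        Lp = _psd_factor(truth.p_true[s])
        devs = rng.standard_normal((n_i, sysm.k)) @ Lp.T
        cs = float(np.exp(log_cs[i]))
        for j in range(n_i):
            lm = sysm.to_landmarks(species_means[i] + devs[j])
            lm = lm + rng.normal(0, noise_sd, lm.shape)
            lm = cs * lm @ _random_rotation(rng) + rng.uniform(-5, 5, 3)
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{s}_{j:03d}", species_id=s, coords=lm
                )
            )
    return configs


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def recovery_angle(
    gpa_result, vector_k: np.ndarray, truth: SyntheticTruth, fold: bool = True
) -> float:
    """Angle (degrees) between an estimated tangent direction and the true
    allometric direction.

    The GPA consensus frame is arbitrarily rotated relative to the
    generator's reference shape, so both directions are mapped to
    landmark-space deformation fields and the consensus is first aligned to
    the reference by orthogonal Procrustes.
    """
    from .procrustes import _optimal_rotation
    from .llr import vector_angle

    sysm = truth.shape_system
    R = _optimal_rotation(gpa_result.consensus, sysm.mean_shape)
    est = (gpa_result.basis @ np.asarray(vector_k, dtype=float)).reshape(-1, 3) @ R
    tru = (sysm.basis @ truth.crea_direction).reshape(-1, 3)
    return vector_angle(est.ravel(), tru.ravel(), fold=fold)


def clades_at_depth(tree: PhyloTree, depth: float) -> dict[str, str]:
    """Label each tip by the clade it belongs to when the tree is cut at
    ``depth`` from the root; tips whose pendant branch spans the cut get
    their own label."""
    dtree = tree._tree
    tree._root_distances()
    labels: dict[str, str] = {}
    counter = [0]

    def assign(node) -> None:
        parent_d = 0.0 if node.parent_node is None else node.parent_node.root_distance
        if node.root_distance >= depth > parent_d or (
            node.is_leaf() and node.root_distance < depth
        ):
            name = f"clade{counter[0]:02d}"
            counter[0] += 1
            for lf in node.leaf_iter():
                labels[lf.taxon.label] = name
            return
        for c in node.child_nodes():
            assign(c)

    assign(dtree.seed_node)
    return labels


def synthetic_taxon_table(
    tree: PhyloTree,
    percent_grass: np.ndarray,
    family_depth: float = 0.2,
    subfamily_depth: float = 0.45,
) -> pd.DataFrame:
    """Trait table with clade-derived family/subfamily labels.

    Families are the clades below the cut at ``family_depth`` (fraction of
    tree depth from the root), subfamilies those at ``subfamily_depth``;
    nesting holds by construction.
    """
    d = tree.depth
    fams = clades_at_depth(tree, family_depth * d)
    subs = clades_at_depth(tree, subfamily_depth * d)
    taxa = tree.taxa
    return pd.DataFrame(
        {
            "species_id": taxa,
            "family": [f"fam_{fams[t]}" for t in taxa],
            "subfamily": [f"sub_{subs[t]}" for t in taxa],
            "percent_grass": np.asarray(percent_grass, dtype=float),
        }
    )


def generate_study(
    n_species: int = 130,
    n_intraspecific: int = 49,
    specimens_range: tuple[int, int] = (27, 60),
    background_range: tuple[int, int] = (3, 15),
    p_landmarks: int = 28,
    noise_sd: float = 0.01,
    seed: int = 0,
    out_dir: str | Path | None = None,
    diet_missing_fraction: float = 0.25,
    **truth_kwargs,
):
    """Generate a complete study bundle (landmarks, tree, traits, truth).

    Intraspecific species get a uniform specimen count from
    ``specimens_range``; the rest draw from ``background_range``.  The
    defaults (49 species at 27-60 specimens, 81 at 3-15) put the expected
    total near 2900 crania over 130 species, the scale of the museum dataset
    this design emulates.  A quarter of species have missing diet data,
    mirroring incomplete ecological sampling.  If ``out_dir`` is given,
    writes landmarks.tps, tree.nwk, taxa.csv and truth.json there.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=6)
    tree = simulate_tree(n_species, seed=int(sub[0]))
    sysm = make_shape_system(p_landmarks, seed=int(sub[1]))
    truth = make_truth(
        tree, sysm, n_intraspecific=n_intraspecific, seed=int(sub[2]), **truth_kwargs
    )
    means, log_cs, grass = simulate_species(tree, truth, seed=int(sub[3]))
    intra_set = set(truth.intraspecific_species)
    n_spec = {
        s: int(rng.integers(specimens_range[0], specimens_range[1] + 1))
        if s in intra_set
        else int(rng.integers(background_range[0], background_range[1] + 1))
        for s in tree.taxa
    }
    configs = simulate_populations(
        means, log_cs, truth, n_spec, noise_sd=noise_sd, seed=int(sub[4])
    )
    taxa = synthetic_taxon_table(tree, grass)
    miss = rng.random(len(taxa)) < diet_missing_fraction
    taxa.loc[miss, "percent_grass"] = np.nan
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_landmarks(configs, out / "landmarks.tps")
        tree.write(out / "tree.nwk")
        taxa.to_csv(out / "taxa.csv", index=False)
        meta = {
            "seed": seed,
            "n_species": n_species,
            "n_intraspecific": n_intraspecific,
            "allometric_slope": truth.allometric_slope,
            "rate_eccentricity": truth.rate_eccentricity,
            "diet_coupling": truth.diet_coupling,
            "llr_coupling": truth.llr_coupling,
            "intraspecific_species": truth.intraspecific_species,
            "alignment_true": truth.alignment_true,
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=2))
    return configs, taxa, tree, truth, means, log_cs
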