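"""Full-analysis orchestration: from a study bundle to the report tables.

Stages: GPA and species means → phylogenetic allometry (CREA vector, RRPP
significance, subfamily slope heterogeneity) → ordinations (PCA/pPCA/PACA,
specimen projection, family densities) → BM rate matrix with confidence
contours → per-species line-of-least-resistance statistics and their PGLS
tests → browser-grazer axis and trend surface.  Every stochastic step derives
its seed from the config seed, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bm, llr, ordination, pgls, procrustes
from .io import AlignedStudy, PhyloTree, assemble_study, read_landmarks, read_taxon_table, read_tree

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis", "exclude_taxa", "load_study"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis.

    Defaults follow the study design the pipeline reproduces: at least 27
    specimens for the intraspecific set, 999 permutations, 499 random vectors
    per species, 10,000 random angles, rate matrix on the first 5 PCs, and
    95/99% confidence contours.
    """

    landmarks: str | None = None
    tree: str | None = None
    taxa: str | None = None
    out_dir: str = "results/report"
    min_n: int = 27
    n_perm: int = 999
    n_random_vectors: int = 499
    n_random_angles: int = 10000
    n_pcs_rate_matrix: int = 5
    ci_levels: tuple[float, ...] = (0.95, 0.99)
    normalize_vproj: bool = True
    fold_angles: bool = False
    log_f_effect_size: bool = False
    subset_family: str | None = None
    exclude: tuple[str, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("min_n", "n_perm", "n_random_vectors", "n_random_angles",
                     "n_pcs_rate_matrix"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(not 0 < lv < 1 for lv in self.ci_levels):
            raise ValueError("ci_levels must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ci_levels" in data:
            data["ci_levels"] = tuple(data["ci_levels"])
        if "exclude" in data:
            data["exclude"] = tuple(data["exclude"])
        return cls(**data)


def load_study(config: AnalysisConfig) -> AlignedStudy:
    configs = read_landmarks(config.landmarks)
    tree = read_tree(config.tree)
    taxa = read_taxon_table(config.taxa)
    return assemble_study(configs, taxa, tree, min_n=config.min_n)


def exclude_taxa(study: AlignedStudy, taxa: list[str]) -> AlignedStudy:
    """Drop species from a study (landmarks + tree), recomputing flags."""
    if not taxa:
        return study
    missing = set(taxa) - set(study.species)
    if missing:
        raise KeyError(f"taxa not in study: {sorted(missing)}")
    keep = [s for s in study.species if s not in set(taxa)]
    if len(keep) < 3:
        raise ValueError("exclusion leaves fewer than 3 species")
    landmarks = [c for c in study.landmarks if c.species_id in set(keep)]
    return assemble_study(landmarks, study.taxa, study.tree.prune_to(keep),
                          min_n=study.min_n)


def _subseed(seed: int, stage: int) -> int:
    return int(np.random.default_rng([seed, stage]).integers(0, 2**31 - 1))


def run_full_analysis(
    config: AnalysisConfig, study: AlignedStudy | None = None
) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of in-memory results keyed by stage; CSV tables and a JSON
    metadata sidecar are written alongside.  A stage failure is logged, the
    partial report is kept, and the error is re-raised by ``strict`` callers
    (the CLI exits nonzero).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = load_study(config)
    if config.subset_family:
        fam_map = dict(zip(study.taxa["species_id"], study.taxa["family"]))
        keep = [s for s in study.species
                if fam_map.get(s, "").lower() == config.subset_family.lower()]
        drop = [s for s in study.species if s not in set(keep)]
        study = exclude_taxa(study, drop)
    if config.exclude:
        study = exclude_taxa(study, list(config.exclude))
    results: dict = {"study": study}

    # ---- stage 1: superimposition and species means -----------------------
    logger.info("GPA on %d specimens", len(study.landmarks))
    g = procrustes.gpa(study.landmarks)
    species, means, log_cs = procrustes.species_means(g)
    # reorder to tree tip order
    order = study.tree.taxa
    idx = [species.index(s) for s in order]
    means, log_cs = means[idx], log_cs[idx]
    results["gpa"] = g
    results["species"] = order
    results["means"] = means
    results["log_cs"] = log_cs

    taxa_df = study.taxa.set_index("species_id")
    subfamily = np.array([taxa_df.loc[s, "subfamily"] for s in order])
    family = np.array([taxa_df.loc[s, "family"] for s in order])
    C_tree = study.tree.vcv(order=order)

    # ---- stage 2: evolutionary allometry ----------------------------------
    X, labels = pgls.design_matrix({"log_cs": log_cs})
    fit = pgls.pgls_fit(means, X, C_tree, design_labels=labels)
    perm = pgls.rrpp_significance(
        fit, n_perm=config.n_perm, seed=_subseed(config.seed, 2),
        log_f=config.log_f_effect_size,
    )
    crea = pgls.allometric_vector(fit, "log_cs")
    allometry_rows = [{
        "term": "log_cs", "df": fit.df_model, "SS": fit.SS_model,
        "R2": fit.R2, "F": fit.F, "Z": perm.Z, "P": perm.P,
    }]
    try:
        het = pgls.slope_heterogeneity_test(
            means, log_cs, subfamily, C_tree,
            n_perm=config.n_perm, seed=_subseed(config.seed, 3),
        )
        allometry_rows.append({
            "term": "log_cs:subfamily", "df": np.nan, "SS": np.nan,
            "R2": np.nan, "F": het.observed, "Z": het.Z, "P": het.P,
        })
    except ValueError as exc:
        logger.warning("slope heterogeneity test skipped: %s", exc)
        het = None
    allometry = pd.DataFrame(allometry_rows)
    allometry.to_csv(out / "allometry.csv", index=False)
    results["allometry_fit"] = fit
    results["allometry_perm"] = perm
    results["crea"] = crea
    results["slope_heterogeneity"] = het

    # ---- stage 3: ordinations --------------------------------------------
    ords = {
        "pca": ordination.pca(means),
        "ppca": ordination.phylo_pca(means, C_tree),
        "paca": ordination.paca(means, C_tree),
    }
    score_tables = []
    for name, o in ords.items():
        df = pd.DataFrame(
            o.scores[:, : min(10, o.m)],
            columns=[f"{name}_axis{j+1}" for j in range(min(10, o.m))],
        )
        df.insert(0, "species_id", order)
        score_tables.append(df.set_index("species_id"))
    pd.concat(score_tables, axis=1).to_csv(out / "ordination_scores.csv")
    results["ordinations"] = ords

    spec_scores = ordination.project_specimens(ords["pca"], g.tangent)
    fam_of = dict(zip(study.taxa["species_id"], study.taxa["family"]))
    densities = ordination.family_density(
        spec_scores[:, 0], g.species_ids, fam_of
    )
    results["specimen_scores"] = spec_scores
    results["family_density_pc1"] = densities

    # ---- stage 4: BM rate matrix and contours -----------------------------
    m = min(config.n_pcs_rate_matrix, ords["pca"].m)
    pc_scores = ords["pca"].scores[:, :m]
    rm = bm.fit_bm_rate_matrix(pc_scores, C_tree)
    depths = study.tree.tip_depths()
    contour_rows, outside = [], {}
    for lv in config.ci_levels:
        dist2 = bm.bm_tip_distribution(rm, float(depths.mean()), axes=[0, 1])
        ell, _ = bm.ci_contour(dist2, lv)
        contour_rows.append({
            "level": lv, "center_1": ell.center[0], "center_2": ell.center[1],
            "semi_major": ell.semi_axes[0], "semi_minor": ell.semi_axes[1],
            "angle_deg": ell.angle_deg,
        })
        # flag species against the contour marginalized to the two plotted
        # axes (the morphospace the ellipses are drawn in)
        flags = []
        for i, s in enumerate(order):
            dist_i = bm.bm_tip_distribution(rm, float(depths[i]), axes=[0, 1])
            _, inside = bm.ci_contour(dist_i, lv)
            flags.append(not bool(inside(pc_scores[i, :2])[0]))
        outside[lv] = flags
    rate_json = {
        "C": rm.C.tolist(), "root": rm.root.tolist(), "m": rm.m,
        "loglik": rm.loglik, "contours": contour_rows,
    }
    (out / "rate_matrix.json").write_text(json.dumps(rate_json, indent=2))
    pd.DataFrame(
        {"species_id": order, **{f"outside_{lv}": outside[lv] for lv in config.ci_levels}}
    ).to_csv(out / "contour_flags.csv", index=False)
    results["rate_matrix"] = rm
    results["outside_contours"] = outside

    # ---- stage 5: line-of-least-resistance statistics ---------------------
    intra = [s for s in order if study.in_intraspecific_set.get(s, False)]
    records: list[llr.LLRRecord] = []
    angle_seed = _subseed(config.seed, 5)
    null = llr.random_angle_null(g.k, n=config.n_random_angles, seed=angle_seed)
    sp_arr = np.asarray(g.species_ids)
    sub_of = dict(zip(order, subfamily))
    anc_cache: dict[str, np.ndarray] = {}
    anc_tan_cache: dict[str, np.ndarray] = {}
    for s in intra:
        tang = g.tangent[sp_arr == s]
        P = llr.p_matrix(tang, species_id=s)
        vproj_raw = llr.projected_variance(P, crea)
        vproj_frac = vproj_raw / P.trace if P.trace > 0 else 0.0
        rnd_mean, _ = llr.random_vector_null(
            P, n_vectors=config.n_random_vectors,
            seed=_subseed(config.seed, 50 + intra.index(s)),
            normalize=config.normalize_vproj,
        )
        vrel, zrel = llr.integration_effect_size(P)
        sub = sub_of[s]
        if sub not in anc_cache:
            members = [t for t in order if sub_of[t] == sub]
            node = (study.tree.mrca_node(members) if len(members) > 1
                    else study.tree.root)
            anc_cache[sub] = bm.ancestral_states(pc_scores, study.tree, node)
            anc_tan_cache[sub] = bm.ancestral_states(means, study.tree, node)
        i = order.index(s)
        D = llr.divergence_magnitude(pc_scores[i], anc_cache[sub])
        dvec, dunit = llr.divergence_vector(means[i], anc_tan_cache[sub])
        if dunit is None:
            theta = np.nan
            vproj_div = np.nan
        else:
            theta = llr.vector_angle(dvec, crea, fold=config.fold_angles)
            vproj_div = llr.projected_variance(
                P, dunit, normalize=config.normalize_vproj
            )
        records.append(llr.LLRRecord(
            species_id=s,
            Vproj_crea=vproj_raw,
            Vproj_crea_frac=vproj_frac,
            Vproj_random_mean=rnd_mean,
            Vproj_divergence=vproj_div,
            Vrel=vrel,
            Zrel=zrel,
            divergence_D=D,
            angle_deg=theta,
            centroid_size=float(np.exp(log_cs[i])),
        ))
    llr_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    llr_df.to_csv(out / "llr_records.csv", index=False)
    results["llr_records"] = llr_df
    results["angle_null"] = null

    pgls_rows = []
    if len(intra) >= 5:
        tree_intra = study.tree.prune_to(intra)
        C_intra = tree_intra.vcv(order=intra)
        D_vec = llr_df.set_index("species_id").loc[intra, "divergence_D"].to_numpy()
        vcol = "Vproj_crea_frac" if config.normalize_vproj else "Vproj_crea"
        predictors = {
            "Vproj_crea": llr_df.set_index("species_id").loc[intra, vcol].to_numpy(),
            "Zrel": llr_df.set_index("species_id").loc[intra, "Zrel"].to_numpy(),
            "angle": llr_df.set_index("species_id").loc[intra, "angle_deg"].to_numpy(),
        }
        for j, (name, x) in enumerate(predictors.items()):
            ok = np.isfinite(x)
            if ok.sum() < 5:
                continue
            Csub = C_intra[np.ix_(ok, ok)]
            sfit, sperm = pgls.pgls_scalar(
                D_vec[ok], x[ok], Csub,
                n_perm=config.n_perm, seed=_subseed(config.seed, 80 + j),
            )
            pgls_rows.append({
                "predictor": name, "slope": sfit.coefficients[1, 0],
                "R2": sfit.R2, "F": sfit.F, "Z": sperm.Z, "P": sperm.P,
            })
        obs_angles = llr_df["angle_deg"].dropna().to_numpy()
        ksD, ksP = llr.ks_angles_vs_null(obs_angles, null)
        results["ks_angles"] = (ksD, ksP)
    else:
        logger.warning("fewer than 5 intraspecific species; divergence PGLS skipped")
        results["ks_angles"] = (np.nan, np.nan)
    divergence_df = pd.DataFrame(pgls_rows)
    divergence_df.to_csv(out / "divergence_pgls.csv", index=False)
    results["divergence_pgls"] = divergence_df

    # ---- stage 6: ecology axis and trend surface --------------------------
    if "percent_grass" in taxa_df.columns:
        grass = np.array(
            [taxa_df["percent_grass"].get(s, np.nan) for s in order], dtype=float
        )
    else:
        grass = np.full(len(order), np.nan)
    ecology: dict = {}
    if np.isfinite(grass).sum() >= 10:
        diet_axis, diet_fit = llr.ecology_axis(means, grass, study.tree, taxa=order)
        theta, P_angle = llr.angle_significance(crea, diet_axis, null=null)
        surf = llr.trend_surface(
            ords["pca"].scores[np.isfinite(grass), :2], grass[np.isfinite(grass)],
            n_perm=config.n_perm, seed=_subseed(config.seed, 6),
        )
        ecology = {
            "angle_crea_diet_deg": theta, "P_angle": P_angle,
            "diet_R2": diet_fit.R2, "surface_R2": surf.R2, "surface_P": surf.P,
            "n_diet_species": int(np.isfinite(grass).sum()),
        }
        results["diet_axis"] = diet_axis
        results["trend_surface"] = surf
    else:
        logger.warning("too few species with diet data; ecology stage skipped")
    results["ecology"] = ecology

    meta = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_interspecific": study.n_interspecific,
        "n_intraspecific": len(intra),
        "tangent_dimension": g.k,
        "gpa_iterations": g.iterations,
        "var_fraction_pca": ords["pca"].var_fraction[:5].tolist(),
        "ks_angles_D": results["ks_angles"][0],
        "ks_angles_P": results["ks_angles"][1],
        "ecology": ecology,
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "report.json").write_text(json.dumps(meta, indent=2, default=float))
    logger.info("report written to %s in %.1fs", out, time.time() - t0)
    return results
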