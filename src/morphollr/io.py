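"""Reading, writing, and reconciling the three study inputs.

A study couples (1) per-specimen 3-D landmark configurations, (2) a rooted
phylogeny with branch lengths, and (3) a per-species trait table (family,
subfamily, optional percent grass in diet).  This module parses the supported
on-disk formats (TPS ``LM3=`` blocks, a long-format landmark CSV, Newick,
trait CSV), validates their invariants, and assembles them into a single
:class:`AlignedStudy` whose species keys agree across all three sources.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "PhyloTree",
    "AlignedStudy",
    "read_landmarks",
    "write_landmarks",
    "read_tree",
    "read_taxon_table",
    "assemble_study",
]


class StudyStructureError(ValueError):
    """Raised when inputs violate a structural invariant (ragged landmark
    counts, duplicate tips, missing branch lengths, zero key overlap)."""


@dataclass
class LandmarkConfiguration:
    """One specimen's raw p x 3 landmark coordinates."""

    specimen_id: str
    species_id: str
    coords: np.ndarray  # (p, 3), length units

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StudyStructureError(
                f"specimen {self.specimen_id!r}: coords must be p x 3, "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 4:
            raise StudyStructureError(
                f"specimen {self.specimen_id!r}: need at least 4 landmarks"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StudyStructureError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


def _check_constant_p(configs: Sequence[LandmarkConfiguration]) -> int:
    p = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != p:
            raise StudyStructureError(
                f"specimen {c.specimen_id!r} has {c.n_landmarks} landmarks, "
                f"expected {p} (landmark count must be constant)"
            )
    return p


# ---------------------------------------------------------------------------
# TPS format: blocks of "LM3=<p>" followed by p whitespace-separated x y z
# lines, then "ID=<specimen>" and "SPECIES=<species>" keys.
# ---------------------------------------------------------------------------

def _parse_tps(text: str, path: str) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise StudyStructureError(
                f"{path}:{i + 1}: expected 'LM3=' block header, got {line!r}"
            )
        try:
            p = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise StudyStructureError(
                f"{path}:{i + 1}: malformed landmark count {line!r}"
            ) from exc
        i += 1
        rows = []
        for j in range(p):
            if i >= len(lines):
                raise StudyStructureError(
                    f"{path}: truncated block, expected {p} landmark rows"
                )
            parts = lines[i].split()
            if len(parts) != 3:
                raise StudyStructureError(
                    f"{path}:{i + 1}: expected 3 coordinates, got {lines[i]!r}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise StudyStructureError(
                    f"{path}:{i + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from exc
            i += 1
        specimen_id = species_id = None
        while i < len(lines) and "=" in lines[i] and not lines[
            i
        ].strip().upper().startswith("LM3="):
            key, _, value = lines[i].strip().partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SPECIES":
                species_id = value.strip()
            i += 1
        if specimen_id is None:
            raise StudyStructureError(f"{path}: block without ID= key")
        configs.append(
            LandmarkConfiguration(specimen_id, species_id or specimen_id, np.array(rows))
        )
    return configs


def _format_tps(configs: Sequence[LandmarkConfiguration]) -> str:
    out = []
    for c in configs:
        out.append(f"LM3={c.n_landmarks}")
        for row in c.coords:
            out.append(" ".join(repr(float(v)) for v in row))
        out.append(f"ID={c.specimen_id}")
        out.append(f"SPECIES={c.species_id}")
    return "\n".join(out) + "\n"


_CSV_COLUMNS = ["specimen_id", "species_id", "landmark_index", "x", "y", "z"]


def read_landmarks(path: str | Path, format: str | None = None) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS or long-format CSV file.

    The CSV dialect has columns ``specimen_id, species_id, landmark_index,
    x, y, z`` with a 0-based landmark index.  The landmark count must be
    identical across specimens.
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        configs = _parse_tps(path.read_text(), str(path))
    elif format == "csv":
        df = pd.read_csv(path)
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise StudyStructureError(f"{path}: missing columns {sorted(missing)}")
        configs = []
        for spec_id, block in df.groupby("specimen_id", sort=False):
            block = block.sort_values("landmark_index")
            idx = block["landmark_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise StudyStructureError(
                    f"{path}: specimen {spec_id!r} has non-contiguous landmark indices"
                )
            species = block["species_id"].iloc[0]
            configs.append(
                LandmarkConfiguration(str(spec_id), str(species), block[["x", "y", "z"]].to_numpy())
            )
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    if not configs:
        raise StudyStructureError(f"{path}: no landmark configurations found")
    _check_constant_p(configs)
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        path.write_text(_format_tps(configs))
    elif format == "csv":
        rows = []
        for c in configs:
            for j, (x, y, z) in enumerate(c.coords):
                rows.append((c.specimen_id, c.species_id, j, x, y, z))
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted phylogeny with branch lengths (My), wrapping a dendropy tree.

    Provides the Brownian-motion covariance structure used throughout:
    ``vcv()[i, j]`` is the root-to-MRCA depth shared by tips i and j.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 3:
            raise StudyStructureError("tree must have at least 3 tips")
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise StudyStructureError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise StudyStructureError(
                    "tree has missing branch lengths (Newick without lengths?)"
                )
            if edge.length < 0:
                raise StudyStructureError("negative branch length")
        self._taxa = labels

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.utility.error.DataParseError as exc:
            raise StudyStructureError(f"malformed or duplicate-label Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick())

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic structure ----------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        """Tip labels in leaf-iteration order (the canonical row order)."""
        return list(self._taxa)

    @property
    def n_tips(self) -> int:
        return len(self._taxa)

    def _root_distances(self) -> None:
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )

    def tip_depths(self) -> np.ndarray:
        self._root_distances()
        order = {t: i for i, t in enumerate(self._taxa)}
        d = np.empty(len(self._taxa))
        for lf in self._tree.leaf_node_iter():
            d[order[lf.taxon.label]] = lf.root_distance
        return d

    @property
    def depth(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.allclose(d, d.max(), rtol=rtol, atol=rtol * max(d.max(), 1.0)))

    # -- BM covariance ------------------------------------------------------

    def vcv(self, order: Sequence[str] | None = None, eps_scale: float = 1e-8) -> np.ndarray:
        """Brownian-motion covariance matrix among tips.

        C[i, j] = depth of the MRCA of tips i and j; C[i, i] = tip depth.
        Zero-length terminal branches are inflated by ``eps_scale * depth``
        (with a warning) to keep C positive definite.
        """
        taxa = list(order) if order is not None else self._taxa
        idx = {t: i for i, t in enumerate(taxa)}
        missing = [t for t in taxa if t not in set(self._taxa)]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        n = len(taxa)
        C = np.zeros((n, n))
        self._root_distances()
        # postorder: record, per node, which requested tips descend from it
        tipsets: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tipsets[node] = [idx[lab]] if lab in idx else []
                if lab in idx:
                    C[idx[lab], idx[lab]] = node.root_distance
            else:
                children = [tipsets[c] for c in node.child_nodes()]
                merged: list[int] = []
                for a_i, a in enumerate(children):
                    for b in children[a_i + 1:]:
                        for i in a:
                            for j in b:
                                C[i, j] = C[j, i] = node.root_distance
                    merged.extend(a)
                tipsets[node] = merged
        # inflate exact ties between distinct tips (zero-length terminals)
        d = np.diag(C).copy()
        off = C - np.diag(d)
        problem = [i for i in range(n) if np.any(np.isclose(off[i], d[i], rtol=0, atol=0))]
        if problem:
            eps = eps_scale * float(d.max())
            for i in problem:
                C[i, i] += eps
            warnings.warn(
                f"{len(problem)} zero-length terminal branches inflated by {eps:g} "
                "to keep the BM covariance invertible"
            )
        return C

    def prune_to(self, taxa: Iterable[str]) -> "PhyloTree":
        keep = set(taxa)
        missing = keep - set(self._taxa)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(tree)

    # -- node access for ancestral-state work --------------------------------

    def mrca_node(self, taxa: Sequence[str]):
        taxon_set = [t for t in self._tree.taxon_namespace if t.label in set(taxa)]
        if len(taxon_set) < len(set(taxa)):
            raise KeyError("mrca query includes taxa not in tree")
        node = self._tree.mrca(taxa=taxon_set)
        if node is None:
            raise KeyError("no MRCA found")
        return node

    @property
    def root(self):
        return self._tree.seed_node

    def node_tip_covariances(self, node) -> np.ndarray:
        """cov(node, tip_i) under BM = depth of MRCA(node, tip_i)."""
        self._root_distances()
        node_leafset = {lf.taxon.label for lf in node.leaf_iter()}
        # walk up from `node`; for tips outside its clade, the MRCA is the
        # first ancestor containing them
        cov = np.empty(self.n_tips)
        anc_chain = [node]
        cur = node
        while cur.parent_node is not None:
            cur = cur.parent_node
            anc_chain.append(cur)
        clade_sets = []
        for a in anc_chain:
            clade_sets.append(({lf.taxon.label for lf in a.leaf_iter()}, a.root_distance))
        for i, t in enumerate(self._taxa):
            if t in node_leafset:
                cov[i] = node.root_distance
            else:
                for labels, depth in clade_sets:
                    if t in labels:
                        cov[i] = depth
                        break
        return cov

    def patristic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        taxa = list(order) if order is not None else self._taxa
        C = self.vcv(order=taxa, eps_scale=0.0)
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2 * C


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    return PhyloTree.read(path)


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

def read_taxon_table(path: str | Path) -> pd.DataFrame:
    """Read the per-species trait table.

    Columns: species_id, family, subfamily, and optionally percent_grass
    (a value in [0, 100], missing allowed).
    """
    df = pd.read_csv(path)
    required = {"species_id", "family", "subfamily"}
    missing = required - set(df.columns)
    if missing:
        raise StudyStructureError(f"{path}: trait table missing {sorted(missing)}")
    if df["species_id"].duplicated().any():
        dupes = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise StudyStructureError(f"{path}: duplicate species_id {dupes}")
    if "percent_grass" in df.columns:
        vals = df["percent_grass"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise StudyStructureError(f"{path}: percent_grass outside [0, 100]")
    # subfamily nested within family
    sub2fam = df.dropna(subset=["subfamily"]).groupby("subfamily")["family"].nunique()
    bad = sub2fam[sub2fam > 1].index.tolist()
    if bad:
        raise StudyStructureError(f"{path}: subfamilies in multiple families: {bad}")
    return df


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

@dataclass
class AlignedStudy:
    """Landmarks, traits and pruned tree reconciled onto one species key.

    ``in_intraspecific_set[s]`` is True iff species ``s`` has at least
    ``min_n`` specimens (default 27), mirroring the split into an
    interspecific dataset of species means and an intraspecific dataset of
    well-sampled species.
    """

    landmarks: list[LandmarkConfiguration]
    taxa: pd.DataFrame
    tree: PhyloTree
    min_n: int = 27
    in_intraspecific_set: dict[str, bool] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return self.tree.taxa

    @property
    def n_interspecific(self) -> int:
        return len(self.species)

    @property
    def n_intraspecific(self) -> int:
        return sum(self.in_intraspecific_set.values())

    def specimen_counts(self) -> pd.Series:
        return pd.Series(
            [c.species_id for c in self.landmarks], name="species_id"
        ).value_counts()


def assemble_study(
    landmarks: Sequence[LandmarkConfiguration],
    taxa: pd.DataFrame,
    tree: PhyloTree,
    min_n: int = 27,
) -> AlignedStudy:
    """Reconcile landmarks, trait table and tree into one study.

    The tree is pruned to species with landmark data; species with landmark
    data but no tip are dropped with a logged warning.  Species with at least
    ``min_n`` specimens are flagged as the intraspecific set.
    """
    landmarks = list(landmarks)
    _check_constant_p(landmarks)
    lm_species = {c.species_id for c in landmarks}
    tree_species = set(tree.taxa)
    common = lm_species & tree_species
    if not common:
        raise StudyStructureError("no species shared between landmarks and tree")
    dropped = sorted(lm_species - tree_species)
    if dropped:
        logger.warning(
            "dropping %d species with landmarks but no tree tip: %s",
            len(dropped), dropped,
        )
        landmarks = [c for c in landmarks if c.species_id in common]
    pruned = tree.prune_to(common) if common != tree_species else tree
    if not pruned.is_ultrametric():
        warnings.warn("tree is not ultrametric; BM depths will vary across tips")
    counts = pd.Series([c.species_id for c in landmarks]).value_counts()
    flags = {s: bool(counts.get(s, 0) >= min_n) for s in pruned.taxa}
    return AlignedStudy(
        landmarks=landmarks, taxa=taxa, tree=pruned, min_n=min_n,
        in_intraspecific_set=flags,
    )
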