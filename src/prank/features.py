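"""Feature vectors for atoms (AFVs) and inner pocket points (IFVs).

Every atom of a standard residue gets an atom feature vector (AFV): the
residue-level features of its parent residue (Kyte–Doolittle hydropathy and
five physico-chemical class indicators) concatenated with atomic-level
features (a one-hot pharmacophore type plus a ligand-binding propensity
column).  The feature vector of an inner point (IFV) is the sum of the AFVs
of the heavy, solvent-exposed protein atoms within the 8 Å neighborhood,
each weighted by w(d) = 1 - d/8, concatenated with four point-specific
features: H-bond donor and acceptor counts in the neighborhood, the mean
B-factor of the neighborhood, and a protrusion (local convexity) index.

All features are local: nothing about the global pocket or protein shape
enters the vector.  The tables live in ``prank/data`` as CSV so they can be
swapped without touching code; the schema version is a content hash, so any
edit to the tables produces datasets and models that refuse to mix with the
defaults.
"""

from __future__ import annotations

import functools
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import PrankConfig
from .model import PointDataset
from .structure_io import Atom, ProteinStructure
from .surface import (
    LABEL_POSITIVE,
    label_points,
    sample_sas_points,
    select_inner_points,
    solvent_exposed_atoms,
)

logger = logging.getLogger(__name__)

PHARMACOPHORE_CLASSES = (
    "hydrophobic", "aromatic", "donor", "acceptor", "donor_acceptor",
    "positive", "negative", "none",
)
DONOR_CLASSES = frozenset({"donor", "donor_acceptor", "positive"})
ACCEPTOR_CLASSES = frozenset({"acceptor", "donor_acceptor", "negative"})

POINT_FEATURE_NAMES = ("n_donors", "n_acceptors", "mean_bfactor", "protrusion")

#: Average volume (Å³) attributed to one heavy atom in the protrusion index.
ATOM_VOLUME = 20.1


@dataclass
class PropertyTables:
    """Versioned residue- and atom-level physico-chemical property tables."""

    residue_table: pd.DataFrame   # index: resname
    atom_table: pd.DataFrame      # index: (resname, atom); one-hot + propensity
    schema_version: str
    _atom_rows: dict[tuple[str, str], int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = set(_STANDARD_RESIDUES) - set(self.residue_table.index)
        if missing:
            raise ValueError(f"residue table lacks standard residues: {sorted(missing)}")
        self._atom_rows = {key: i for i, key in enumerate(self.atom_table.index)}

    @property
    def residue_feature_names(self) -> list[str]:
        return [f"res_{c}" for c in self.residue_table.columns]

    @property
    def atom_feature_names(self) -> list[str]:
        return [f"atom_{c}" for c in self.atom_table.columns]

    @property
    def afv_feature_names(self) -> list[str]:
        return self.residue_feature_names + self.atom_feature_names

    @property
    def feature_names(self) -> list[str]:
        """Full IFV schema: aggregated AFV block then point-specific block."""
        return self.afv_feature_names + list(POINT_FEATURE_NAMES)

    @property
    def n_afv(self) -> int:
        return len(self.residue_table.columns) + len(self.atom_table.columns)

    def pharmacophore_class(self, resname: str, atom_name: str) -> str | None:
        i = self._atom_rows.get((resname, atom_name))
        if i is None:
            return None
        onehot = self.atom_table.iloc[i]
        for cls in PHARMACOPHORE_CLASSES:
            if onehot[f"ph_{cls}"] == 1:
                return cls
        return None

    @classmethod
    def from_files(cls, residue_csv, atom_csv) -> "PropertyTables":
        res_raw = Path(residue_csv).read_bytes()
        atm_raw = Path(atom_csv).read_bytes()
        version = "tables-" + hashlib.sha256(res_raw + atm_raw).hexdigest()[:12]
        residue_table = pd.read_csv(residue_csv).set_index("resname").astype(float)
        atoms = pd.read_csv(atom_csv)
        onehot = pd.DataFrame(
            {f"ph_{c}": (atoms["pharmacophore"] == c).astype(float)
             for c in PHARMACOPHORE_CLASSES})
        unknown = set(atoms["pharmacophore"]) - set(PHARMACOPHORE_CLASSES)
        if unknown:
            raise ValueError(f"unknown pharmacophore classes: {sorted(unknown)}")
        atom_table = pd.concat(
            [onehot, atoms[["propensity"]].astype(float)], axis=1)
        atom_table.index = pd.MultiIndex.from_frame(atoms[["resname", "atom"]])
        return cls(residue_table=residue_table, atom_table=atom_table,
                   schema_version=version)

    @classmethod
    @functools.cache
    def default(cls) -> "PropertyTables":
        data = resources.files("prank.data")
        return cls.from_files(data / "residue_table.csv", data / "atom_table.csv")


_STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_warned_lookups: set[tuple[str, str]] = set()


def weight(d):
    """Distance weight w(d) = 1 - d/8 for d in [0, 8] Å (scalar or array)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 8):
        raise ValueError("distance outside the [0, 8] Å neighborhood domain")
    out = 1.0 - d / 8.0
    return float(out) if out.ndim == 0 else out


def compute_afv(atom: Atom, tables: PropertyTables) -> np.ndarray:
    """Residue-level features of the atom's residue ‖ its atomic features.

    Unknown residues or (residue, atom) pairs fall back to zeros with a
    logged warning — never an error.
    """
    resname = atom.resname
    n_res = len(tables.residue_table.columns)
    n_atm = len(tables.atom_table.columns)
    if resname in tables.residue_table.index:
        res_part = tables.residue_table.loc[resname].to_numpy(dtype=float)
    else:
        res_part = np.zeros(n_res)
        _warn_once((resname, ""), "unknown residue %r: zero residue features", resname)
    row = tables._atom_rows.get((resname, atom.name))
    if row is not None:
        atm_part = tables.atom_table.iloc[row].to_numpy(dtype=float)
    else:
        atm_part = np.zeros(n_atm)
        _warn_once((resname, atom.name),
                   "unknown atom (%r, %r): zero atomic features", resname, atom.name)
    return np.concatenate([res_part, atm_part])


def _warn_once(key, msg, *args) -> None:
    if key not in _warned_lookups:
        _warned_lookups.add(key)
        logger.warning(msg, *args)


def atomic_neighborhood(point, exposed_serials, structure: ProteinStructure,
                        radius: float = 8.0) -> list[tuple[Atom, float]]:
    """Heavy, solvent-exposed polymer atoms within ``radius`` Å (inclusive)."""
    point = np.asarray(point, dtype=float)
    out = []
    for atom in structure.atoms:
        if atom.serial not in exposed_serials:
            continue
        d = float(np.linalg.norm(atom.coords - point))
        if d <= radius:
            out.append((atom, d))
    return out


def protrusion_index(point, structure: ProteinStructure, R: float = 10.0,
                     cap: float = 15.0) -> float:
    """Local convexity: (V_sphere - N*v_atom) / (N*v_atom), capped.

    N counts heavy protein atoms within ``R`` Å of the point; large values
    mean an exposed, convex locale, small values a buried or concave one.
    An empty sphere returns the cap.
    """
    point = np.asarray(point, dtype=float)
    d = np.linalg.norm(structure.coords - point, axis=1)
    n = int((d <= R).sum())
    return _protrusion_from_count(n, R, cap)


def _protrusion_from_count(n, R: float, cap: float):
    v_sphere = 4.0 / 3.0 * np.pi * R**3
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(n > 0, (v_sphere - n * ATOM_VOLUME) / (n * ATOM_VOLUME), cap)
    out = np.minimum(ratio, cap)
    return float(out) if out.ndim == 0 else out


def compute_point_features(point, structure: ProteinStructure,
                           neighborhood: list[tuple[Atom, float]],
                           tables: PropertyTables | None = None,
                           config: PrankConfig | None = None) -> np.ndarray:
    """Point-specific feature block: donors, acceptors, mean B, protrusion."""
    tables = tables or PropertyTables.default()
    config = config or PrankConfig()
    donors = acceptors = 0
    b_factors = []
    for atom, _ in neighborhood:
        cls = tables.pharmacophore_class(atom.resname, atom.name)
        if cls in DONOR_CLASSES:
            donors += 1
        if cls in ACCEPTOR_CLASSES:
            acceptors += 1
        b_factors.append(atom.b_factor)
    mean_b = float(np.mean(b_factors)) if b_factors else 0.0
    prot = protrusion_index(point, structure, R=config.protrusion_radius,
                            cap=config.protrusion_cap)
    return np.array([donors, acceptors, mean_b, prot], dtype=float)


def aggregate_ifv(neighborhood: list[tuple[Atom, float]],
                  tables: PropertyTables, fv: np.ndarray) -> np.ndarray:
    """Distance-weighted AFV sum over the neighborhood, concatenated with fv.

    An empty neighborhood contributes a zero AFV block.
    """
    agg = np.zeros(tables.n_afv)
    for atom, d in neighborhood:
        afv = compute_afv(atom, tables)
        if len(afv) != tables.n_afv:
            raise ValueError("AFV length mismatch within one schema")
        agg += afv * weight(d)
    return np.concatenate([agg, np.asarray(fv, dtype=float)])


class FeaturizationContext:
    """Per-structure precomputation shared by all of its pockets.

    Builds the exposed-atom AFV matrix, donor/acceptor indicator vectors and
    the KD-trees once, then featurizes point batches vectorized.
    """

    def __init__(self, structure: ProteinStructure, tables: PropertyTables,
                 exposed_serials: frozenset[int], config: PrankConfig):
        self.structure = structure
        self.tables = tables
        self.config = config
        exposed_idx = [i for i, a in enumerate(structure.atoms)
                       if a.serial in exposed_serials]
        self._exposed_atoms = [structure.atoms[i] for i in exposed_idx]
        self._exposed_coords = structure.coords[exposed_idx]
        self._afv = np.array([compute_afv(a, tables) for a in self._exposed_atoms]) \
            if exposed_idx else np.zeros((0, tables.n_afv))
        classes = [tables.pharmacophore_class(a.resname, a.name)
                   for a in self._exposed_atoms]
        self._is_donor = np.array([c in DONOR_CLASSES for c in classes], dtype=float)
        self._is_acceptor = np.array([c in ACCEPTOR_CLASSES for c in classes], dtype=float)
        self._bfac = np.array([a.b_factor for a in self._exposed_atoms], dtype=float)
        self._exposed_tree = cKDTree(self._exposed_coords) if exposed_idx else None
        self._all_tree = cKDTree(structure.coords)

    def featurize(self, coords: np.ndarray) -> np.ndarray:
        """IFV rows for a batch of point coordinates."""
        cfg = self.config
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = len(coords)
        out = np.zeros((n, self.tables.n_afv + len(POINT_FEATURE_NAMES)))
        n_afv = self.tables.n_afv
        if self._exposed_tree is not None and n > 0:
            neigh = self._exposed_tree.query_ball_point(
                coords, cfg.neighborhood_radius, workers=-1)
            for i, idx in enumerate(neigh):
                if not idx:
                    continue
                idx = np.asarray(idx)
                d = np.linalg.norm(self._exposed_coords[idx] - coords[i], axis=1)
                w = weight(np.minimum(d, cfg.neighborhood_radius))
                out[i, :n_afv] = w @ self._afv[idx]
                out[i, n_afv + 0] = self._is_donor[idx].sum()
                out[i, n_afv + 1] = self._is_acceptor[idx].sum()
                out[i, n_afv + 2] = self._bfac[idx].mean()
        if n > 0:
            counts = self._all_tree.query_ball_point(
                coords, cfg.protrusion_radius, workers=-1, return_length=True)
            out[:, n_afv + 3] = _protrusion_from_count(
                counts, cfg.protrusion_radius, cfg.protrusion_cap)
        return out


def build_point_dataset(corpus, tables: PropertyTables | None = None,
                        config: PrankConfig | None = None,
                        strict: bool = False) -> PointDataset:
    """Sample, select, label and featurize inner points for a whole corpus.

    ``corpus`` yields ``(structure, pockets)`` pairs; ligands are taken from
    each structure.  One output row per (pocket, inner point).  Per-protein
    failures are skipped with a log entry unless ``strict``.
    """
    tables = tables or PropertyTables.default()
    config = config or PrankConfig()
    X_parts, y_parts, group_parts, meta_rows = [], [], [], []
    for structure, pockets in corpus:
        try:
            sas = sample_sas_points(structure, probe=config.probe_radius,
                                    tess_level=config.tess_level)
            exposed = solvent_exposed_atoms(structure, points=sas)
            ctx = FeaturizationContext(structure, tables, exposed, config)
            for pocket in pockets:
                inner = select_inner_points(sas, pocket, structure,
                                            belt=config.inner_belt)
                inner = label_points(inner, structure.ligands,
                                     threshold=config.label_threshold)
                if len(inner) == 0:
                    continue
                X_parts.append(ctx.featurize(inner.coords))
                y_parts.append((inner.labels == LABEL_POSITIVE).astype(int))
                group_parts.append(np.full(len(inner), structure.id, dtype=object))
                for x, y, z in inner.coords:
                    meta_rows.append({"protein_id": structure.id,
                                      "pocket_id": pocket.pocket_id,
                                      "x": x, "y": y, "z": z})
        except Exception:
            if strict:
                raise
            logger.exception("skipping protein %r", structure.id)
    if not X_parts:
        raise ValueError("corpus produced no inner points")
    return PointDataset(
        X=np.vstack(X_parts),
        y=np.concatenate(y_parts),
        groups=np.concatenate(group_parts),
        feature_names=tables.feature_names,
        schema_version=tables.schema_version,
        meta=pd.DataFrame(meta_rows),
    )
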