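"""Self-contained synthetic fixtures: toy globular proteins with a planted
binding site, decoy pockets, labeled point datasets, and whole benchmark
corpora.

A toy protein is a pseudo-globular heavy-atom shell (two concentric layers
of jittered sphere points, each atom emitted as its own one-atom residue
with a plausible residue/atom name) with one concave crater.  The crater
lining is drawn from a donor/acceptor/aromatic-rich "ligandable"
composition and its B-factors are shifted by ``effect_size`` standard
deviations, so the planted site carries both a geometric signal (concavity,
hence low protrusion index) and a chemical one.  A ring-shaped ligand of
``ligand_size`` heavy atoms sits inside the crater; by construction the
planted pocket passes the 4 Å D_CA criterion for it, while decoy pockets
(centered on convex surface patches at least 10 Å from the ligand) cannot.

Everything is deterministic for a fixed seed, and the emitted PDB text
round-trips through :func:`prank.structure_io.load_structure`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import (
    Ligand,
    PocketPrediction,
    ProteinStructure,
    load_structure,
    parse_generic_pockets,
    write_generic_pockets,
)
from .model import PointDataset

__all__ = [
    "FixtureSpec",
    "make_toy_protein",
    "make_decoy_pockets",
    "make_point_dataset",
    "make_benchmark",
    "load_benchmark",
    "make_benchmark_corpus",
]

# --- frozen geometry of the toy globule (Å / rad) -------------------------
CAP_ANGLE = 0.55          # angular aperture of the crater
LINING_FRAC = 0.8         # lining atoms lie within LINING_FRAC * CAP_ANGLE
CRATER_DEPTH = 4.5        # radial depth of the crater floor
SHELL_SPACING = 2.9       # target spacing between shell atoms
INNER_SHELL_OFFSET = 3.0  # second layer sits this far below the surface
LIGAND_CLEARANCE = 3.2    # ligand plane height above the crater floor
LIGAND_RING_RADIUS = 1.9
B_MEAN, B_SD = 20.0, 5.0  # B-factor distribution; lining shifted by
                          # effect_size * B_SD

# donor/acceptor/aromatic-rich lining composition vs. mixed background
LIGANDABLE_PAIRS = (
    ("TRP", "NE1"), ("TYR", "OH"), ("HIS", "ND1"), ("ARG", "NH1"),
    ("SER", "OG"), ("ASN", "OD1"), ("GLN", "NE2"), ("LYS", "NZ"),
)
BACKGROUND_PAIRS = (
    ("ALA", "CB"), ("LEU", "CD1"), ("VAL", "CG1"), ("ILE", "CD1"),
    ("GLY", "CA"), ("PRO", "CG"), ("THR", "CG2"), ("MET", "SD"),
    ("PHE", "CZ"), ("GLU", "OE1"), ("ASP", "OD1"), ("SER", "CB"),
    ("CYS", "SG"), ("LYS", "CD"), ("ARG", "CG"), ("THR", "OG1"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic benchmark."""

    seed: int = 0
    n_proteins: int = 10
    n_decoys_per_protein: int = 4
    effect_size: float = 1.5     # lining B-factor shift, in units of B_SD
    ligand_size: int = 8         # heavy atoms in the ring ligand
    globule_radius: float = 16.0
    noise_sd: float = 0.3        # radial jitter of shell atoms

    def __post_init__(self) -> None:
        if self.effect_size < 0 or self.n_decoys_per_protein < 0:
            raise ValueError("effect_size and n_decoys must be non-negative")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spaced unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _pdb_atom_line(record: str, serial: int, name: str, resname: str,
                   chain: str, resseq: int, xyz, b: float) -> str:
    pname = name if len(name) == 4 else f" {name:<3s}"
    x, y, z = xyz
    return (f"{record:<6s}{serial:>5d} {pname}{'':1s}{resname:>3s} {chain}"
            f"{resseq:>4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
            f"{b:6.2f}          {_element_of(name):>2s}")


def _shell_count(radius: float) -> int:
    return max(12, int(round(4.0 * np.pi * radius**2 / SHELL_SPACING**2)))


def make_toy_protein(spec: FixtureSpec, index: int
                     ) -> tuple[str, PocketPrediction, Ligand]:
    """Build one toy protein; returns (PDB text, planted pocket, ligand).

    The planted pocket's members are the crater-lining atoms; its center is
    their centroid.  Byte-identical output for a fixed (seed, index).
    """
    rng = np.random.default_rng([spec.seed, index])
    R = spec.globule_radius
    rot = _random_rotation(rng)

    dirs_outer = _fibonacci_sphere(_shell_count(R))
    dirs_inner = _fibonacci_sphere(_shell_count(R - INNER_SHELL_OFFSET))

    coords, lining_flags = [], []
    for dirs, base_r in ((dirs_outer, R), (dirs_inner, R - INNER_SHELL_OFFSET)):
        theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
        depth = np.where(
            theta < CAP_ANGLE,
            CRATER_DEPTH * 0.5 * (1.0 + np.cos(np.pi * theta / CAP_ANGLE)),
            0.0,
        )
        radial = base_r - depth + rng.normal(0.0, spec.noise_sd, len(dirs))
        coords.append(dirs * radial[:, None])
        lining_flags.append((theta <= LINING_FRAC * CAP_ANGLE)
                            & (base_r == R))
    coords = np.vstack(coords)
    lining = np.concatenate(lining_flags)

    n = len(coords)
    b_factors = rng.normal(B_MEAN, B_SD, n)
    b_factors[lining] += spec.effect_size * B_SD
    b_factors = np.clip(b_factors, 0.1, None)

    pair_idx = rng.integers(0, len(BACKGROUND_PAIRS), n)
    lig_pair_idx = rng.integers(0, len(LIGANDABLE_PAIRS), n)

    # ring ligand inside the crater, in the canonical (+z) frame
    floor = R - CRATER_DEPTH
    angles = 2.0 * np.pi * np.arange(spec.ligand_size) / spec.ligand_size
    lig_coords = np.column_stack([
        LIGAND_RING_RADIUS * np.cos(angles),
        LIGAND_RING_RADIUS * np.sin(angles),
        np.full(spec.ligand_size, floor + LIGAND_CLEARANCE),
    ])

    coords = coords @ rot.T
    lig_coords = lig_coords @ rot.T

    lines = [f"HEADER    SYNTHETIC GLOBULE {spec.seed}-{index}"]
    for i in range(n):
        resname, atom_name = (
            LIGANDABLE_PAIRS[lig_pair_idx[i]] if lining[i]
            else BACKGROUND_PAIRS[pair_idx[i]]
        )
        lines.append(_pdb_atom_line("ATOM", i + 1, atom_name, resname, "A",
                                    i + 1, coords[i], b_factors[i]))
    for j in range(spec.ligand_size):
        lines.append(_pdb_atom_line("HETATM", n + 1 + j, f"C{j + 1}", "LIG",
                                    "L", 9000, lig_coords[j], B_MEAN))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    lining_serials = frozenset((np.flatnonzero(lining) + 1).tolist())
    lining_coords = coords[lining]
    true_pocket = PocketPrediction(
        pocket_id="true",
        original_rank=1,
        member_atom_serials=lining_serials,
        center=lining_coords.mean(axis=0),
    )
    from .structure_io import Atom  # local import to avoid clutter above
    ligand = Ligand(
        atoms=[Atom(serial=n + 1 + j, element="C", name=f"C{j + 1}",
                    coords=lig_coords[j], residue_key=("L", 9000, "", "LIG"),
                    b_factor=B_MEAN, is_hetero=True)
               for j in range(spec.ligand_size)],
        group_name="LIG",
    )
    return pdb_text, true_pocket, ligand


def make_decoy_pockets(structure: ProteinStructure,
                       true_pocket: PocketPrediction,
                       n: int, seed: int) -> list[PocketPrediction]:
    """The planted pocket plus ``n`` decoys, with randomized original ranks.

    Decoys are centered on convex surface patches whose member centroid is
    at least 10 Å from every ligand atom; volumes are drawn iid for decoys
    and the true pocket alike, so neither the original order nor the volume
    baseline encodes the answer.
    """
    rng = np.random.default_rng([seed, 7])
    lig_coords = (np.vstack([l.coords for l in structure.ligands])
                  if structure.ligands else np.zeros((0, 3)))

    def min_lig_dist(points: np.ndarray) -> float:
        if len(lig_coords) == 0:
            return np.inf
        diffs = points[:, None, :] - lig_coords[None, :, :]
        return float(np.sqrt((diffs**2).sum(-1)).min())

    coords = structure.coords
    serials = np.asarray([a.serial for a in structure.atoms])
    candidate = [i for i in range(len(coords))
                 if min_lig_dist(coords[i:i + 1]) >= 13.0]
    rng.shuffle(candidate)

    decoys: list[PocketPrediction] = []
    picked_centers: list[np.ndarray] = []
    for i in candidate:
        if len(decoys) == n:
            break
        c = coords[i]
        if any(np.linalg.norm(c - p) < 8.0 for p in picked_centers):
            continue
        member_mask = np.linalg.norm(coords - c, axis=1) <= 5.0
        members = serials[member_mask]
        centroid = coords[member_mask].mean(axis=0)
        if min_lig_dist(coords[member_mask]) < 10.0:
            continue
        picked_centers.append(c)
        decoys.append(PocketPrediction(
            pocket_id=f"decoy{len(decoys) + 1}",
            original_rank=1,  # reassigned below
            member_atom_serials=frozenset(members.tolist()),
            center=centroid,
        ))
    if len(decoys) < n:
        raise RuntimeError(f"could only place {len(decoys)}/{n} decoy pockets")

    pockets = [true_pocket] + decoys
    ranks = rng.permutation(len(pockets)) + 1
    volumes = rng.uniform(100.0, 400.0, len(pockets))
    out = [
        PocketPrediction(
            pocket_id=p.pocket_id,
            original_rank=int(ranks[i]),
            member_atom_serials=p.member_atom_serials,
            center=p.center,
            volume=float(volumes[i]),
        )
        for i, p in enumerate(pockets)
    ]
    out.sort(key=lambda p: p.original_rank)
    return out


def make_point_dataset(n_pos: int = 125, n_neg: int = 1875,
                       effect_size: float = 2.0, n_features: int = 16,
                       seed: int = 0, n_shifted: int = 5,
                       n_groups: int = 10) -> PointDataset:
    """Abstract labeled point dataset with a controllable mean shift.

    Features are unit-variance Gaussians; positive rows are shifted by
    ``effect_size`` on the first ``n_shifted`` features.  The default 15:1
    negative:positive imbalance matches what realistic candidate-pocket
    corpora produce.  Rows carry round-robin pseudo-protein group keys for
    grouped cross-validation.
    """
    rng = np.random.default_rng([seed, 11])
    n = n_pos + n_neg
    X = rng.normal(size=(n, n_features))
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    X[:n_pos, :n_shifted] += effect_size
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    groups = np.array([f"G{i % n_groups:02d}" for i in range(n)], dtype=object)
    return PointDataset(
        X=X, y=y, groups=groups,
        feature_names=[f"f{i}" for i in range(n_features)],
        schema_version=f"synthetic-gauss-{n_features}",
    )


def make_benchmark(spec: FixtureSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full corpus (PDBs + pocket CSVs + manifest) to ``out_dir``.

    Returns the manifest with columns protein_id, pdb, pockets, n_ligands;
    the same frame is written to ``out_dir/manifest.csv``.  Re-running with
    the same spec produces byte-identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "pocket_lists").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(spec.n_proteins):
        pid = f"p{i:03d}"
        pdb_text, true_pocket, _ = make_toy_protein(spec, i)
        pdb_path = out_dir / "structures" / f"{pid}.pdb"
        pdb_path.write_text(pdb_text)
        structure = load_structure(pdb_path, structure_id=pid)
        pockets = make_decoy_pockets(structure, true_pocket,
                                     spec.n_decoys_per_protein,
                                     seed=spec.seed * 100003 + i)
        pockets_path = out_dir / "pocket_lists" / f"{pid}_pockets.csv"
        write_generic_pockets(pockets, pockets_path)
        rows.append({"protein_id": pid,
                     "pdb": str(pdb_path.relative_to(out_dir)),
                     "pockets": str(pockets_path.relative_to(out_dir)),
                     "n_ligands": len(structure.ligands)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_benchmark(manifest_path: str | Path
                   ) -> list[tuple[ProteinStructure, list[PocketPrediction]]]:
    """Load a written benchmark back as (structure, pockets) pairs."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    corpus = []
    for row in manifest.itertuples(index=False):
        structure = load_structure(base / row.pdb, structure_id=row.protein_id)
        pockets = parse_generic_pockets(base / row.pockets, structure)
        corpus.append((structure, pockets))
    return corpus


def make_benchmark_corpus(spec: FixtureSpec
                          ) -> list[tuple[ProteinStructure, list[PocketPrediction]]]:
    """In-memory benchmark corpus (same content as :func:`make_benchmark`).

    Goes through the PDB text and the same pocket construction, so it is
    exactly what a write/load round trip would produce.
    """
    import tempfile
    corpus = []
    with tempfile.TemporaryDirectory() as tmp:
        for i in range(spec.n_proteins):
            pid = f"p{i:03d}"
            pdb_text, true_pocket, _ = make_toy_protein(spec, i)
            path = Path(tmp) / f"{pid}.pdb"
            path.write_text(pdb_text)
            structure = load_structure(path, structure_id=pid)
            pockets = make_decoy_pockets(structure, true_pocket,
                                         spec.n_decoys_per_protein,
                                         seed=spec.seed * 100003 + i)
            corpus.append((structure, pockets))
    return corpus
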