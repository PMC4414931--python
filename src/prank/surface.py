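"""Solvent-accessible surface point sampling and inner-point selection.

Each heavy atom contributes the vertices of a subdivided icosahedron
(tessellation level k -> 10*4**k + 2 vertices) scaled to its expanded
radius r_vdw + probe.  Vertices strictly inside any other atom's expanded
sphere are discarded, leaving evenly spaced points on the solvent-accessible
surface.  Points within the inner belt (default 4 Å, inclusive) of a
pocket's heavy atoms become that pocket's inner points — the classification
units of the method.  Inner points are labeled ligandable (positive) when
they lie within the label threshold (default 2.5 Å, inclusive) of any heavy
ligand atom.
"""

from __future__ import annotations

import csv
import functools
import itertools
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Ligand, PocketPrediction, ProteinStructure

logger = logging.getLogger(__name__)

#: Numerical tolerance (Å) of the occlusion test; a vertex is discarded only
#: when it is more than this distance inside another expanded sphere.
OCCLUSION_TOL = 1e-6

LABEL_UNLABELED, LABEL_NEGATIVE, LABEL_POSITIVE = -1, 0, 1


@functools.cache
def _vdw_table() -> dict[str, float]:
    with resources.files("prank.data").joinpath("vdw_radii.csv").open() as fh:
        return {row["element"]: float(row["radius"]) for row in csv.DictReader(fh)}


DEFAULT_VDW_RADIUS = 1.70
_warned_elements: set[str] = set()


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) from the bundled table; unknown -> 1.70."""
    table = _vdw_table()
    el = element.upper()
    if el in table:
        return table[el]
    if el not in _warned_elements:
        _warned_elements.add(el)
        logger.warning("unknown element %r: using default vdW radius %.2f Å",
                       element, DEFAULT_VDW_RADIUS)
    return DEFAULT_VDW_RADIUS


@functools.cache
def icosphere_vertices(level: int) -> np.ndarray:
    """Unit-sphere vertices of a level-``level`` subdivided icosahedron.

    Vertex count is 10*4**level + 2; the array is read-only and cached.
    """
    if level < 0:
        raise ValueError("tessellation level must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.asarray(v, dtype=float) / np.linalg.norm(v) for v in verts]

    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in midpoint_cache:
            m = verts[i] + verts[j]
            verts.append(m / np.linalg.norm(m))
            midpoint_cache[key] = len(verts) - 1
        return midpoint_cache[key]

    for _ in range(level):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    out = np.asarray(verts)
    out.setflags(write=False)
    return out


@dataclass
class SurfacePoints:
    """Array-backed collection of accessible surface points.

    ``coords[i]`` lies at distance r_vdw + probe from the atom with serial
    ``parent_serials[i]`` and is not strictly inside any other atom's
    expanded sphere.
    """

    coords: np.ndarray          # (N, 3)
    parent_serials: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class InnerPoints:
    """Inner points of one pocket, with optional labels/features/P1."""

    pocket_id: str
    coords: np.ndarray                 # (N, 3)
    parent_serials: np.ndarray         # (N,)
    labels: np.ndarray | None = None   # int8 in {-1, 0, 1}
    features: np.ndarray | None = None
    p1: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coords)


def _expanded_radii(structure: ProteinStructure, probe: float) -> np.ndarray:
    return np.asarray([vdw_radius(a.element) + probe for a in structure.atoms])


def sample_sas_points(structure: ProteinStructure, probe: float = 1.6,
                      tess_level: int = 2) -> SurfacePoints:
    """Sample evenly spaced solvent-accessible surface points.

    Returns the surviving icosphere vertices over all heavy polymer atoms;
    ligand (HETATM) atoms neither generate nor occlude points.
    """
    atoms = structure.coords
    radii = _expanded_radii(structure, probe)
    unit = icosphere_vertices(tess_level)
    n_atoms, n_verts = len(atoms), len(unit)

    # all candidate vertices: (n_atoms*n_verts, 3)
    pts = (atoms[:, None, :] + radii[:, None, None] * unit[None, :, :])
    pts = pts.reshape(-1, 3)
    parent = np.repeat(np.arange(n_atoms), n_verts)

    tree = cKDTree(atoms)
    r_max = radii.max()
    neigh = tree.query_ball_point(pts, r_max, workers=-1)
    counts = np.fromiter((len(v) for v in neigh), dtype=np.intp, count=len(neigh))
    pt_idx = np.repeat(np.arange(len(pts)), counts)
    at_idx = np.fromiter(itertools.chain.from_iterable(neigh), dtype=np.intp,
                         count=int(counts.sum()))
    d = np.linalg.norm(pts[pt_idx] - atoms[at_idx], axis=1)
    inside = (d < radii[at_idx] - OCCLUSION_TOL) & (at_idx != parent[pt_idx])
    occluded = np.zeros(len(pts), dtype=bool)
    occluded[pt_idx[inside]] = True

    keep = ~occluded
    serials = np.asarray([a.serial for a in structure.atoms])
    return SurfacePoints(coords=pts[keep], parent_serials=serials[parent[keep]])


def solvent_exposed_atoms(structure: ProteinStructure, probe: float = 1.6,
                          tess_level: int = 2,
                          points: SurfacePoints | None = None) -> frozenset[int]:
    """Serials of atoms with at least one surviving surface vertex."""
    if points is None:
        points = sample_sas_points(structure, probe=probe, tess_level=tess_level)
    return frozenset(np.unique(points.parent_serials).tolist())


def select_inner_points(points: SurfacePoints, pocket: PocketPrediction,
                        structure: ProteinStructure,
                        belt: float = 4.0) -> InnerPoints:
    """Retain surface points within ``belt`` Å (inclusive) of pocket atoms.

    A surface point adjacent to several pockets is retained independently
    for each, so pocket scores do not interact.
    """
    member_atoms = structure.atoms_by_serials(sorted(pocket.member_atom_serials))
    member_coords = np.asarray([a.coords for a in member_atoms])
    if len(points) == 0:
        keep = np.zeros(0, dtype=bool)
    else:
        tree = cKDTree(member_coords)
        dist, _ = tree.query(points.coords, k=1)
        keep = dist <= belt
    return InnerPoints(
        pocket_id=pocket.pocket_id,
        coords=points.coords[keep],
        parent_serials=points.parent_serials[keep],
    )


def label_points(inner: InnerPoints, ligands: list[Ligand],
                 threshold: float = 2.5) -> InnerPoints:
    """Label inner points by proximity to heavy ligand atoms.

    Positive iff the minimum distance to any heavy ligand atom (over all
    ligands) is <= ``threshold``; with no ligands every point is negative.
    The class ratio is reported as-is — no rebalancing anywhere downstream.
    """
    if threshold <= 0:
        raise ValueError("label threshold must be positive")
    labels = np.full(len(inner), LABEL_NEGATIVE, dtype=np.int8)
    if ligands and len(inner) > 0:
        lig_coords = np.vstack([lig.coords for lig in ligands])
        dist, _ = cKDTree(lig_coords).query(inner.coords, k=1)
        labels[dist <= threshold] = LABEL_POSITIVE
    return replace(inner, labels=labels)


def write_points_debug(inner: InnerPoints, path: str | Path) -> None:
    """Write points as an XYZ-style table with label and P1 columns."""
    n = len(inner)
    labels = inner.labels if inner.labels is not None else np.full(n, LABEL_UNLABELED)
    p1 = inner.p1 if inner.p1 is not None else np.full(n, np.nan)
    with open(path, "w") as fh:
        fh.write("x y z pocket_id label p1\n")
        for i in range(n):
            x, y, z = inner.coords[i]
            fh.write(f"{x:.3f} {y:.3f} {z:.3f} {inner.pocket_id} "
                     f"{int(labels[i])} {p1[i]:.4f}\n")
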