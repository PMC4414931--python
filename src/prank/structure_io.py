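"""Reading protein structures and candidate pocket lists; writing rankings.

Structures are read from PDB files via gemmi with a heavy-atom-only
contract: hydrogens (and deuteriums) never reach downstream code.  HETATM
groups that are not on the ignore list and have at least ``min_ligand_atoms``
heavy atoms become relevant ligands for the ligand-centric evaluation.

Candidate pockets come either from an Fpocket-style output directory
(``pockets/pocketN_atm.pdb`` files) or from a generic CSV dialect::

    pocket_id,rank,score,volume,atom_serials[,cx,cy,cz]

where ``atom_serials`` is a ';'-joined list of atom serial numbers of the
parent structure and an explicit center (cx,cy,cz) overrides the member-atom
centroid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Ligand",
    "ProteinStructure",
    "PocketPrediction",
    "StructureParseError",
    "EmptyStructureError",
    "PocketFormatError",
    "CrossReferenceError",
    "DEFAULT_IGNORE_GROUPS",
    "load_structure",
    "parse_fpocket_output",
    "parse_generic_pockets",
    "write_generic_pockets",
    "write_rescored",
]


class StructureParseError(ValueError):
    """The input file could not be parsed as a PDB structure."""


class EmptyStructureError(ValueError):
    """The structure contains no heavy polymer atoms."""


class PocketFormatError(ValueError):
    """A pocket list violates its format contract."""


class CrossReferenceError(ValueError):
    """A pocket references atom serials absent from the structure."""


#: Waters plus common monoatomic ions and cryoprotectants/buffer molecules
#: that never count as relevant ligands.
DEFAULT_IGNORE_GROUPS = frozenset({
    "HOH", "DOD", "WAT",
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD",
    "BR", "IOD",
    "SO4", "PO4", "NO3", "ACT", "ACY", "FMT",
    "GOL", "EDO", "PEG", "MPD", "DMS", "TRS",
})


@dataclass(frozen=True, slots=True)
class Atom:
    """A single heavy atom.

    ``residue_key`` is ``(chain, residue number, insertion code, residue
    name)`` and uniquely identifies the parent residue within a structure.
    """

    serial: int
    element: str
    name: str
    coords: np.ndarray
    residue_key: tuple[str, int, str, str]
    b_factor: float
    is_hetero: bool

    @property
    def resname(self) -> str:
        return self.residue_key[3]


@dataclass(slots=True)
class Ligand:
    """A relevant HETATM group (heavy atoms only)."""

    atoms: list[Atom]
    group_name: str

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand must have at least one atom")

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    @property
    def center(self) -> np.ndarray:
        """Centroid of the heavy ligand atoms."""
        return self.coords.mean(axis=0)


@dataclass
class ProteinStructure:
    """Heavy polymer atoms of one protein plus its relevant ligands."""

    atoms: list[Atom]
    ligands: list[Ligand]
    id: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)
    _serial_index: dict[int, int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} has no polymer atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureParseError(f"structure {self.id!r} has duplicate atom serials")

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.asarray([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def serial_index(self) -> dict[int, int]:
        """Map atom serial -> row index into ``coords`` / ``atoms``."""
        if self._serial_index is None:
            self._serial_index = {a.serial: i for i, a in enumerate(self.atoms)}
        return self._serial_index

    def atoms_by_serials(self, serials) -> list[Atom]:
        idx = self.serial_index
        missing = [s for s in serials if s not in idx]
        if missing:
            raise CrossReferenceError(
                f"atom serials not in structure {self.id!r}: {sorted(missing)}")
        return [self.atoms[idx[s]] for s in serials]


@dataclass
class PocketPrediction:
    """One candidate pocket as emitted by an upstream detection tool."""

    pocket_id: str
    original_rank: int
    member_atom_serials: frozenset[int]
    center: np.ndarray
    original_score: float | None = None
    volume: float | None = None

    def __post_init__(self) -> None:
        if not self.member_atom_serials:
            raise PocketFormatError(f"pocket {self.pocket_id!r} has no member atoms")
        self.member_atom_serials = frozenset(int(s) for s in self.member_atom_serials)
        self.center = np.asarray(self.center, dtype=float)


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties -> file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winners
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def load_structure(
    path: str | Path,
    ignore_list: frozenset[str] | set[str] = DEFAULT_IGNORE_GROUPS,
    min_ligand_atoms: int = 5,
    structure_id: str | None = None,
) -> ProteinStructure:
    """Read a PDB file into a heavy-atom :class:`ProteinStructure`.

    Hydrogens/deuteriums and ignore-listed groups are dropped; alternate
    locations are resolved to the highest-occupancy conformer; only model 1
    of multi-model files is used.  HETATM groups with at least
    ``min_ligand_atoms`` heavy atoms become :class:`Ligand` entries.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    polymer: list[Atom] = []
    het_groups: dict[tuple[str, int, str, str], list[Atom]] = {}
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            is_het = residue.het_flag == "H"
            if is_het and resname in ignore_list:
                continue
            key = (chain.name, residue.seqid.num,
                   residue.seqid.icode.strip(), resname)
            for gatom in _resolve_altlocs(residue):
                el = gatom.element.name.upper()
                if el in ("H", "D"):
                    continue
                atom = Atom(
                    serial=gatom.serial,
                    element=el,
                    name=gatom.name.strip(),
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    residue_key=key,
                    b_factor=float(gatom.b_iso),
                    is_hetero=is_het,
                )
                if is_het:
                    het_groups.setdefault(key, []).append(atom)
                else:
                    polymer.append(atom)

    ligands = [
        Ligand(atoms=atoms, group_name=key[3])
        for key, atoms in het_groups.items()
        if len(atoms) >= min_ligand_atoms
    ]
    sid = structure_id if structure_id is not None else path.stem
    if not polymer:
        raise EmptyStructureError(f"{path}: no heavy polymer atoms")
    return ProteinStructure(atoms=polymer, ligands=ligands, id=sid)


_POCKET_FILE_RE = re.compile(r"pocket(\d+)_atm\.pdb$")


def parse_fpocket_output(directory: str | Path,
                         structure: ProteinStructure) -> list[PocketPrediction]:
    """Parse an Fpocket-style output directory into pocket predictions.

    Expects ``<directory>/pockets/pocketN_atm.pdb`` files whose ATOM/HETATM
    serials reference atoms of ``structure`` and whose HEADER records may
    carry ``Pocket Score`` and ``Volume`` values.  The pocket index N gives
    the original rank.
    """
    directory = Path(directory)
    pockets_dir = directory / "pockets"
    if not pockets_dir.is_dir():
        raise PocketFormatError(f"missing pockets/ subdirectory under {directory}")
    entries = []
    for f in pockets_dir.iterdir():
        m = _POCKET_FILE_RE.search(f.name)
        if m:
            entries.append((int(m.group(1)), f))
    if not entries:
        raise PocketFormatError(f"no pocketN_atm.pdb files under {pockets_dir}")
    entries.sort()

    pockets = []
    for rank, f in entries:
        serials: list[int] = []
        score = volume = None
        for line in f.read_text().splitlines():
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                serials.append(int(line[6:11]))
            elif line.startswith("HEADER") and ":" in line:
                lower = line.lower()
                try:
                    value = float(line.rsplit(":", 1)[1])
                except ValueError:
                    continue
                if "score" in lower and score is None:
                    score = value
                elif "volume" in lower and volume is None:
                    volume = value
        atoms = structure.atoms_by_serials(serials)
        center = np.mean([a.coords for a in atoms], axis=0)
        pockets.append(PocketPrediction(
            pocket_id=f"pocket{rank}",
            original_rank=rank,
            member_atom_serials=frozenset(serials),
            center=center,
            original_score=score,
            volume=volume,
        ))
    _check_rank_contiguity(pockets)
    return pockets


def _check_rank_contiguity(pockets: list[PocketPrediction]) -> None:
    ranks = sorted(p.original_rank for p in pockets)
    if ranks != list(range(1, len(pockets) + 1)):
        raise PocketFormatError(f"ranks are not a contiguous 1..K permutation: {ranks}")


def parse_generic_pockets(path: str | Path,
                          structure: ProteinStructure) -> list[PocketPrediction]:
    """Parse the generic pocket CSV dialect (see module docstring)."""
    df = pd.read_csv(path, dtype={"pocket_id": str})
    required = {"pocket_id", "rank", "atom_serials"}
    if not required.issubset(df.columns):
        raise PocketFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["pocket_id"].duplicated().any():
        dup = df.loc[df["pocket_id"].duplicated(), "pocket_id"].tolist()
        raise PocketFormatError(f"{path}: duplicate pocket_id {dup}")
    has_center = {"cx", "cy", "cz"}.issubset(df.columns)

    pockets = []
    for row in df.itertuples(index=False):
        serials = [int(s) for s in str(row.atom_serials).split(";") if s]
        atoms = structure.atoms_by_serials(serials)
        if has_center and np.isfinite([row.cx, row.cy, row.cz]).all():
            center = np.array([row.cx, row.cy, row.cz], dtype=float)
        else:
            center = np.mean([a.coords for a in atoms], axis=0)
        score = getattr(row, "score", None)
        volume = getattr(row, "volume", None)
        pockets.append(PocketPrediction(
            pocket_id=str(row.pocket_id),
            original_rank=int(row.rank),
            member_atom_serials=frozenset(serials),
            center=center,
            original_score=None if score is None or pd.isna(score) else float(score),
            volume=None if volume is None or pd.isna(volume) else float(volume),
        ))
    _check_rank_contiguity(pockets)
    pockets.sort(key=lambda p: p.original_rank)
    return pockets


def write_generic_pockets(pockets: list[PocketPrediction], path: str | Path) -> None:
    """Write pockets in the generic CSV dialect (round-trips with the parser)."""
    rows = []
    for p in sorted(pockets, key=lambda p: p.original_rank):
        rows.append({
            "pocket_id": p.pocket_id,
            "rank": p.original_rank,
            "score": p.original_score,
            "volume": p.volume,
            "atom_serials": ";".join(str(s) for s in sorted(p.member_atom_serials)),
            "cx": p.center[0], "cy": p.center[1], "cz": p.center[2],
        })
    cols = ["pocket_id", "rank", "score", "volume", "atom_serials", "cx", "cy", "cz"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_rescored(ranked, path: str | Path) -> None:
    """Write a re-ranked pocket list as CSV, sorted by new rank."""
    rows = [{
        "pocket_id": r.pocket.pocket_id,
        "original_rank": r.pocket.original_rank,
        "new_rank": r.new_rank,
        "pscore": r.pscore,
        "n_inner_points": r.n_points,
    } for r in sorted(ranked, key=lambda r: r.new_rank)]
    cols = ["pocket_id", "original_rank", "new_rank", "pscore", "n_inner_points"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
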