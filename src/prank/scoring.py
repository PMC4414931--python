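"""Pocket scoring and re-ranking, plus the PLB and volume baseline rankers.

The pocket score is the cumulative sum of squared positive-class
probabilities over the pocket's inner points: squaring emphasizes points
predicted with high confidence, and not dividing by the point count keeps
oversized-but-correct pockets competitive (extra low-probability points add
almost nothing).  Pockets are reordered by decreasing score; ties keep the
upstream tool's original order.
"""

from __future__ import annotations

import csv
import functools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from joblib import Parallel, delayed

from .config import PrankConfig
from .features import FeaturizationContext, PropertyTables
from .model import TrainedModel, predict_p1
from .structure_io import PocketPrediction, ProteinStructure
from .surface import (
    InnerPoints,
    sample_sas_points,
    select_inner_points,
    solvent_exposed_atoms,
)

__all__ = [
    "RankedPocket",
    "pscore",
    "rank_pockets",
    "rescore_pockets",
    "rescore_many",
    "plb_score",
    "volume_score",
    "default_plb_propensities",
]


@dataclass
class RankedPocket:
    """A pocket with its new score and position after re-ranking."""

    pocket: PocketPrediction
    pscore: float
    new_rank: int
    n_points: int


def pscore(p1s) -> float:
    """Cumulative pocket score: sum of squared P1 over inner points."""
    p1s = np.asarray(p1s, dtype=float)
    if p1s.size and (np.any(p1s < 0) or np.any(p1s > 1)):
        raise ValueError("P1 values must lie in [0, 1]")
    # fsum: correctly rounded, so zero-probability padding is exactly neutral
    return math.fsum(np.square(p1s).tolist())


def rank_pockets(pockets: list[PocketPrediction], scores,
                 n_points=None) -> list[RankedPocket]:
    """Order pockets by decreasing score, stable in original rank.

    Input pockets may come in any order; the output is a permutation of the
    input with contiguous new ranks 1..K.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(pockets):
        raise ValueError("one score per pocket required")
    if n_points is None:
        n_points = np.zeros(len(pockets), dtype=int)
    by_original = sorted(range(len(pockets)),
                         key=lambda i: pockets[i].original_rank)
    order = sorted(by_original, key=lambda i: -scores[i])  # stable
    return [
        RankedPocket(pocket=pockets[i], pscore=float(scores[i]),
                     new_rank=rank, n_points=int(n_points[i]))
        for rank, i in enumerate(order, start=1)
    ]


def rescore_pockets(structure: ProteinStructure,
                    pockets: list[PocketPrediction],
                    model: TrainedModel,
                    tables: PropertyTables | None = None,
                    config: PrankConfig | None = None,
                    return_points: bool = False):
    """Run the full chain: sample -> select -> featurize -> predict -> rank.

    A pocket with zero inner points is kept with score 0 (it sorts last
    among zero-score pockets by its original rank) — re-ranking never drops
    or invents pockets.
    """
    tables = tables or PropertyTables.default()
    config = config or PrankConfig()
    model.check_schema(tables.schema_version)

    sas = sample_sas_points(structure, probe=config.probe_radius,
                            tess_level=config.tess_level)
    exposed = solvent_exposed_atoms(structure, points=sas)
    ctx = FeaturizationContext(structure, tables, exposed, config)

    scores, counts, per_pocket_points = [], [], []
    for pocket in pockets:
        inner = select_inner_points(sas, pocket, structure, belt=config.inner_belt)
        if len(inner) > 0:
            X = ctx.featurize(inner.coords)
            p1 = predict_p1(model, X)
        else:
            p1 = np.zeros(0)
        scores.append(pscore(p1))
        counts.append(len(inner))
        if return_points:
            per_pocket_points.append(InnerPoints(
                pocket_id=pocket.pocket_id, coords=inner.coords,
                parent_serials=inner.parent_serials, p1=p1))
    ranked = rank_pockets(pockets, scores, counts)
    if return_points:
        return ranked, per_pocket_points
    return ranked


def rescore_many(items, model: TrainedModel,
                 tables: PropertyTables | None = None,
                 config: PrankConfig | None = None,
                 n_jobs: int | None = None) -> list[list[RankedPocket]]:
    """Rescore many (structure, pockets) pairs, optionally concurrently.

    Per-protein work is independent; results are returned in input order
    and are identical for any worker count.
    """
    tables = tables or PropertyTables.default()
    config = config or PrankConfig()
    n_jobs = config.n_jobs if n_jobs is None else n_jobs
    if n_jobs == 1:
        return [rescore_pockets(s, p, model, tables, config) for s, p in items]
    return Parallel(n_jobs=n_jobs, backend="threading")(
        delayed(rescore_pockets)(s, p, model, tables, config) for s, p in items)


@functools.cache
def default_plb_propensities() -> dict[str, float]:
    """Bundled per-residue ligand-binding propensities (stand-in values)."""
    with resources.files("prank.data").joinpath("plb_propensities.csv").open() as fh:
        return {row["resname"]: float(row["propensity"])
                for row in csv.DictReader(fh)}


def plb_score(pocket: PocketPrediction, structure: ProteinStructure,
              propensities: dict[str, float] | None = None) -> float:
    """Propensity-for-ligand-binding score of a pocket.

    Mean ligand-binding propensity over the distinct residues that
    contribute member atoms; residues missing from the table count as 0.
    """
    propensities = propensities if propensities is not None else default_plb_propensities()
    atoms = structure.atoms_by_serials(sorted(pocket.member_atom_serials))
    residues = {a.residue_key for a in atoms}
    if not residues:
        raise ValueError(f"pocket {pocket.pocket_id!r} has no lining residues")
    return float(np.mean([propensities.get(key[3], 0.0) for key in residues]))


def volume_score(pocket: PocketPrediction) -> float:
    """Declared pocket volume, or the member atom count when absent."""
    if pocket.volume is not None:
        return float(pocket.volume)
    return float(len(pocket.member_atom_serials))
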