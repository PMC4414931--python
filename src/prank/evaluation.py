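"""Ligand-centric evaluation of pocket rankings.

A (protein, ligand) pair counts as identified at a cutoff when at least one
pocket among the top ``cutoff`` re-ranked pockets passes the detection
criterion for that ligand.  Two criteria are supported, both with inclusive
thresholds (default 4 Å):

* D_CA — minimal distance between the pocket center and any heavy ligand
  atom (the standard criterion);
* D_CC — distance between the pocket center and the ligand centroid
  (compensates for ligand size).

Success rates are reported for the Top-n and Top-(n+2) cutoffs, where n is
the number of relevant ligands of the protein that owns the evaluated
ligand, and for all pockets (total coverage — the ceiling any re-ranking
can reach).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import RankedPocket
from .structure_io import Ligand

__all__ = [
    "ALL_POCKETS",
    "EvalCriterion",
    "EvalReport",
    "dca",
    "dcc",
    "criterion_distance",
    "ligand_identified",
    "success_rates",
    "threshold_sweep",
]

#: Sentinel cutoff meaning "consider every predicted pocket".
ALL_POCKETS = None


@dataclass(frozen=True)
class EvalCriterion:
    kind: str = "DCA"            # "DCA" or "DCC"
    threshold: float = 4.0       # Å, inclusive

    def __post_init__(self) -> None:
        if self.kind not in ("DCA", "DCC"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("criterion threshold must be positive")


def dca(pocket_center, ligand: Ligand) -> float:
    """Minimal distance from the pocket center to any heavy ligand atom."""
    center = np.asarray(pocket_center, dtype=float)
    return float(np.linalg.norm(ligand.coords - center, axis=1).min())


def dcc(pocket_center, ligand: Ligand) -> float:
    """Distance from the pocket center to the ligand centroid."""
    center = np.asarray(pocket_center, dtype=float)
    return float(np.linalg.norm(ligand.center - center))


def criterion_distance(criterion: EvalCriterion, pocket_center,
                       ligand: Ligand) -> float:
    return (dca if criterion.kind == "DCA" else dcc)(pocket_center, ligand)


def ligand_identified(ranked: list[RankedPocket], ligand: Ligand,
                      criterion: EvalCriterion,
                      cutoff: int | None = ALL_POCKETS) -> bool:
    """True iff a pocket among the top ``cutoff`` passes the criterion."""
    if cutoff is not None and cutoff < 1:
        raise ValueError("cutoff must be >= 1 or ALL_POCKETS")
    pockets = sorted(ranked, key=lambda r: r.new_rank)
    if cutoff is not None:
        pockets = pockets[:cutoff]
    return any(
        criterion_distance(criterion, r.pocket.center, ligand)
        <= criterion.threshold
        for r in pockets
    )


@dataclass
class EvalReport:
    """Per-(protein, ligand) outcomes and the three aggregate rates."""

    table: pd.DataFrame          # protein_id, ligand, n_ligands, top_n, top_n2, all
    criterion: EvalCriterion

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def rate_top_n(self) -> float:
        return float(self.table["top_n"].mean())

    @property
    def rate_top_n2(self) -> float:
        return float(self.table["top_n2"].mean())

    @property
    def rate_all(self) -> float:
        return float(self.table["all"].mean())

    def summary(self) -> dict:
        return {
            "criterion": self.criterion.kind,
            "threshold": self.criterion.threshold,
            "n_pairs": self.n_pairs,
            "top_n": self.rate_top_n,
            "top_n2": self.rate_top_n2,
            "all": self.rate_all,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def success_rates(results, criterion: EvalCriterion = EvalCriterion()) -> EvalReport:
    """Ligand-centric success rates over a corpus.

    ``results`` yields ``(protein_id, ligands, ranked_pockets)`` triples.
    For every ligand the cutoff n is the number of relevant ligands of its
    own protein (no cross-protein pooling).
    """
    rows = []
    for protein_id, ligands, ranked in results:
        n = len(ligands)
        for j, ligand in enumerate(ligands):
            rows.append({
                "protein_id": protein_id,
                "ligand": f"{ligand.group_name}:{j}",
                "n_ligands": n,
                "top_n": ligand_identified(ranked, ligand, criterion, n),
                "top_n2": ligand_identified(ranked, ligand, criterion, n + 2),
                "all": ligand_identified(ranked, ligand, criterion, ALL_POCKETS),
            })
    if not rows:
        raise ValueError("empty evaluation corpus")
    return EvalReport(table=pd.DataFrame(rows), criterion=criterion)


def threshold_sweep(results, kind: str = "DCA",
                    thresholds=range(1, 11)) -> pd.DataFrame:
    """Success rates across a range of criterion thresholds.

    Returns one row per threshold with Top-n / Top-(n+2) / all rates.
    """
    results = list(results)
    rows = []
    for t in thresholds:
        report = success_rates(results, EvalCriterion(kind=kind, threshold=float(t)))
        rows.append(report.summary())
    return pd.DataFrame(rows)
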