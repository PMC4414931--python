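"""Runtime configuration for the pocket re-ranking pipeline.

All numeric defaults of the method live here so that a single config object
can be passed through the pipeline, serialized to YAML, and round-tripped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PrankConfig:
    """Numeric defaults of the re-ranking method.

    Attributes
    ----------
    probe_radius
        Solvent probe radius in Å used for accessible-surface point sampling.
    tess_level
        Icosphere tessellation level; level k places 10*4**k + 2 vertices on
        each atom sphere.
    inner_belt
        Maximum distance (Å, inclusive) from a surface point to the nearest
        heavy pocket atom for the point to count as an inner pocket point.
    label_threshold
        Maximum distance (Å, inclusive) from an inner point to any heavy
        ligand atom for the point to be labeled ligandable (positive).
    neighborhood_radius
        Radius (Å, inclusive) of the local atomic neighborhood whose atom
        feature vectors are distance-weighted into the point feature vector.
    protrusion_radius
        Radius (Å) of the sphere used for the protrusion (local convexity)
        index.
    protrusion_cap
        Upper bound applied to the protrusion index (guards the empty-sphere
        case).
    min_ligand_atoms
        Minimum number of heavy atoms for a HETATM group to count as a
        relevant ligand.
    n_trees
        Number of trees in the random forest.
    seed
        Seed for every stochastic step (forest training, cross-validation
        shuffles, fixture generation).
    n_jobs
        Worker count for per-protein rescoring; results are identical for
        any value.
    """

    probe_radius: float = 1.6
    tess_level: int = 2
    inner_belt: float = 4.0
    label_threshold: float = 2.5
    neighborhood_radius: float = 8.0
    protrusion_radius: float = 10.0
    protrusion_cap: float = 15.0
    min_ligand_atoms: int = 5
    n_trees: int = 100
    seed: int = 42
    n_jobs: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrankConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
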