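"""Shared fixtures: bare structures built in code and a small synthetic
benchmark corpus with a trained model, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from prank.config import PrankConfig
from prank.features import PropertyTables, build_point_dataset
from prank.model import train
from prank.structure_io import Atom, Ligand, ProteinStructure
from prank.synth import FixtureSpec, make_benchmark_corpus


def build_structure(coords, resnames=None, atom_names=None, elements=None,
                    b_factors=None, ligand_coords=None, structure_id="test"):
    """Assemble a ProteinStructure directly from arrays (one-atom residues)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    resnames = resnames or ["ALA"] * n
    atom_names = atom_names or ["CB"] * n
    elements = elements or [name[0] for name in atom_names]
    b_factors = b_factors if b_factors is not None else [20.0] * n
    atoms = [
        Atom(serial=i + 1, element=elements[i], name=atom_names[i],
             coords=np.asarray(coords[i], dtype=float),
             residue_key=("A", i + 1, "", resnames[i]),
             b_factor=float(b_factors[i]), is_hetero=False)
        for i in range(n)
    ]
    ligands = []
    if ligand_coords is not None:
        ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
        lig_atoms = [
            Atom(serial=n + 1 + j, element="C", name=f"C{j + 1}",
                 coords=ligand_coords[j], residue_key=("L", 9000, "", "LIG"),
                 b_factor=20.0, is_hetero=True)
            for j in range(len(ligand_coords))
        ]
        ligands = [Ligand(atoms=lig_atoms, group_name="LIG")]
    return ProteinStructure(atoms=atoms, ligands=ligands, id=structure_id)


@pytest.fixture(scope="session")
def tables():
    return PropertyTables.default()


@pytest.fixture(scope="session")
def config():
    return PrankConfig()


@pytest.fixture(scope="session")
def small_corpus():
    """Eight toy proteins with planted sites and four decoys each."""
    spec = FixtureSpec(seed=5, n_proteins=8, n_decoys_per_protein=4,
                       effect_size=1.5)
    return make_benchmark_corpus(spec)


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    return build_point_dataset(small_corpus[:4])


@pytest.fixture(scope="session")
def small_model(small_dataset):
    return train(small_dataset, n_trees=50, seed=5)
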