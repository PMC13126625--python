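"""Shared fixtures: ideal-geometry molecules and hand-built pockets."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from fragmint.refine import PocketModel


def build_mol(smiles: str, coords: np.ndarray | None = None) -> Chem.Mol:
    """Molecule from SMILES, optionally with explicit heavy-atom coordinates."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    if coords is not None:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(np.asarray(coords, float)):
            conf.SetAtomPosition(i, p.tolist())
        mol.AddConformer(conf, assignId=True)
    return mol


def ideal_benzene(z: float = 0.0) -> Chem.Mol:
    """Benzene with a perfect 1.396 Å hexagon in the z-plane."""
    ang = np.radians(90 + 60 * np.arange(6))
    coords = np.stack(
        [1.396 * np.cos(ang), 1.396 * np.sin(ang), np.full(6, z)], axis=1
    )
    return build_mol("c1ccccc1", coords)


def single_atom_mol(element: str = "C", position=(0.0, 0.0, 0.0)) -> Chem.Mol:
    em = Chem.RWMol()
    em.AddAtom(Chem.Atom(element))
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, tuple(float(x) for x in position))
    mol.AddConformer(conf)
    return mol


def make_pocket(
    elements: list[int],
    coords: np.ndarray,
    res_names: list[str] | None = None,
    atom_names: list[str] | None = None,
    res_ids: list[int] | None = None,
) -> PocketModel:
    """Hand-built pocket from raw atom arrays (one chain, default GLY CA atoms)."""
    n = len(elements)
    coords = np.asarray(coords, float).reshape(n, 3)
    return PocketModel(
        elements=np.asarray(elements),
        coords=coords,
        res_ids=np.asarray(res_ids if res_ids is not None else range(1, n + 1)),
        res_names=np.asarray(res_names if res_names is not None else ["GLY"] * n),
        chains=np.asarray(["A"] * n),
        atom_names=np.asarray(atom_names if atom_names is not None else ["CA"] * n),
        center=coords.mean(axis=0),
        radius=10.0,
    )


def empty_pocket() -> PocketModel:
    return PocketModel(
        elements=np.empty(0, int),
        coords=np.empty((0, 3)),
        res_ids=np.empty(0, int),
        res_names=np.empty(0, object),
        chains=np.empty(0, object),
        atom_names=np.empty(0, object),
        center=np.zeros(3),
        radius=10.0,
    )


@pytest.fixture(scope="session")
def toy():
    from fragmint.fixtures import make_toy_complex

    return make_toy_complex(seed=0, n_queries=4)


@pytest.fixture(scope="session")
def toy_pocket(toy):
    return toy.pocket()
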