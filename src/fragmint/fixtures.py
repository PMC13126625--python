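"""Deterministic synthetic test systems: a toy pocket with congeneric ligands.

The toy complex is a rigid, format-valid PDB receptor (a shell of glycine
residues around a cavity) holding a rigid trisubstituted-benzene template
ligand. Query ligands are congeneric analogs produced by swapping one
substituent while keeping the shared-core coordinates fixed, so each query's
true pose is known by construction (core RMSD 0). The scored-pose dataset
plants a known linear metric→success relationship for testing the weight
optimizer. Everything regenerates bit-identically from a seed; none of it is
physically realistic binding thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from fragmint.chemprep import StandardLigand
from fragmint.config import ScoringWeights
from fragmint.refine import PocketModel, pocket_from_structure
from fragmint.templates import TemplateEntry, TemplatePool

_RING_RADIUS = 1.396  # aromatic C–C ring geometry, Å
# substituent element, C–X bond length (Å); first entry is the template's.
# Elements never repeat the fixed methyl/hydroxyl substituents, so every
# series member is asymmetric and its true pose is unambiguous.
_SUBSTITUENTS = [
    ("Cl", 1.74), ("F", 1.35), ("Br", 1.90), ("N", 1.40), ("S", 1.77), ("I", 2.10),
]


def _build_trisubstituted_benzene(x_element: str, x_bond: float) -> Chem.Mol:
    """Benzene with CH3 at ring position 0, OH at position 2, X at position 4.

    The asymmetric substitution pattern breaks ring symmetry so the correct
    superposition is unambiguous. Ring and fixed-substituent coordinates are
    identical for every member of the series; only the X atom differs (same
    direction, element-typical bond length).
    """
    em = Chem.RWMol()
    ring = [em.AddAtom(Chem.Atom(6)) for _ in range(6)]
    for i in range(6):
        em.AddBond(ring[i], ring[(i + 1) % 6], Chem.BondType.AROMATIC)
        em.GetAtomWithIdx(ring[i]).SetIsAromatic(True)
    c_me = em.AddAtom(Chem.Atom(6))  # methyl at position 0
    em.AddBond(ring[0], c_me, Chem.BondType.SINGLE)
    o_oh = em.AddAtom(Chem.Atom(8))  # hydroxyl at position 2
    em.AddBond(ring[2], o_oh, Chem.BondType.SINGLE)
    x = em.AddAtom(Chem.Atom(x_element))  # variable substituent at position 4
    em.AddBond(ring[4], x, Chem.BondType.SINGLE)
    mol = em.GetMol()
    Chem.SanitizeMol(mol)

    conf = Chem.Conformer(mol.GetNumAtoms())
    angles = np.radians(90 + 60 * np.arange(6))
    ring_xy = _RING_RADIUS * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    for i in range(6):
        conf.SetAtomPosition(i, (float(ring_xy[i, 0]), float(ring_xy[i, 1]), 0.0))

    def place(sub_idx: int, ring_pos: int, bond: float):
        direction = ring_xy[ring_pos] / np.linalg.norm(ring_xy[ring_pos])
        p = ring_xy[ring_pos] + bond * direction
        conf.SetAtomPosition(sub_idx, (float(p[0]), float(p[1]), 0.0))

    place(c_me, 0, 1.50)
    place(o_oh, 2, 1.36)
    place(x, 4, x_bond)
    mol.AddConformer(conf, assignId=True)
    return mol


def _as_standard_ligand(mol: Chem.Mol) -> StandardLigand:
    """Wrap a posed fixture molecule, hydrogens added with coordinates."""
    heavy = Chem.Mol(mol)
    mol_h = Chem.AddHs(Chem.Mol(mol), addCoords=True)
    key = Chem.MolToInchiKey(heavy)
    lig = StandardLigand(mol=Chem.RemoveHs(heavy), key=key, mol3d=mol_h)
    lig.energies = [0.0] * mol_h.GetNumConformers()
    return lig


# idealized glycine backbone (N, CA, C, O) in a local frame, Å
_GLY_LOCAL = np.array(
    [[0.0, 0.0, 0.0], [1.46, 0.0, 0.0], [2.0, 1.33, 0.0], [1.38, 2.38, 0.2]]
)
_GLY_NAMES = ["N", "CA", "C", "O"]
_GLY_ELEMENTS = ["N", "C", "C", "O"]


def _receptor_atoms(seed: int, n_residues: int = 10, shell_radius: float = 7.5):
    """Glycine shell around the origin as a biotite AtomArray."""
    import biotite.structure as struc

    rng = np.random.default_rng(seed)
    atoms = struc.AtomArray(n_residues * 4)
    coords = np.zeros((n_residues * 4, 3))
    in_plane = n_residues - 2
    centers = []
    for k in range(in_plane):
        ang = 2 * np.pi * k / in_plane
        centers.append(shell_radius * np.array([np.cos(ang), np.sin(ang), 0.0]))
    centers.append(np.array([0.0, 0.0, shell_radius * 0.85]))
    centers.append(np.array([0.0, 0.0, -shell_radius * 0.85]))
    for r, center in enumerate(centers):
        # deterministic per-residue orientation jitter
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = rng.uniform(0, 2 * np.pi)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        local = (_GLY_LOCAL - _GLY_LOCAL.mean(axis=0)) @ R.T
        for a in range(4):
            i = r * 4 + a
            coords[i] = center + local[a]
            atoms.chain_id[i] = "A"
            atoms.res_id[i] = r + 1
            atoms.res_name[i] = "GLY"
            atoms.atom_name[i] = _GLY_NAMES[a]
            atoms.element[i] = _GLY_ELEMENTS[a]
            atoms.hetero[i] = False
    atoms.coord = np.round(coords, 3)  # PDB precision so files round-trip exactly
    return atoms


@dataclass
class ToyComplex:
    """A synthetic rigid pocket with a template ligand and congeneric queries."""

    seed: int
    receptor: object  # biotite AtomArray
    template: StandardLigand
    template_structure_id: str
    queries: list[StandardLigand]
    true_poses: list[Chem.Mol] = field(default_factory=list)  # H-explicit ground truth

    def pocket(self, radius: float = 8.0) -> PocketModel:
        coords = self.template.heavy_coords(0)
        return pocket_from_structure(self.receptor, coords, radius)

    def template_pool(self, include_queries: bool = False) -> TemplatePool:
        """Pool holding the template crystal pose (optionally the query poses too)."""
        entries = [
            TemplateEntry(ligand=self.template, structure_id=self.template_structure_id)
        ]
        if include_queries:
            for i, q in enumerate(self.queries):
                entries.append(TemplateEntry(ligand=q, structure_id=f"TOYQ{i:02d}"))
        return TemplatePool(protein_id="TOY00001", entries=entries)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit receptor PDB, template/query SDF and an index CSV."""
        import biotite.structure.io.pdb as pdb_io

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        pdb_file = pdb_io.PDBFile()
        pdb_io.set_structure(pdb_file, self.receptor)
        paths["receptor"] = directory / "receptor.pdb"
        pdb_file.write(str(paths["receptor"]))
        paths["ligands"] = directory / "ligands.sdf"
        writer = Chem.SDWriter(str(paths["ligands"]))
        rows = []
        for name, lig in [("template", self.template)] + [
            (f"query_{i}", q) for i, q in enumerate(self.queries)
        ]:
            mol = Chem.Mol(lig.mol3d)
            mol.SetProp("_Name", name)
            mol.SetProp("identity_key", lig.key)
            writer.write(mol)
            rows.append({"name": name, "identity_key": lig.key, "smiles": Chem.MolToSmiles(lig.mol)})
        writer.close()
        paths["index"] = directory / "index.csv"
        pd.DataFrame(rows).to_csv(paths["index"], index=False)
        return paths


def make_toy_complex(seed: int = 0, n_queries: int = 4) -> ToyComplex:
    """Build the deterministic toy complex.

    ``n_queries`` ≤ 5 congeneric analogs of the chloro template; every query
    shares the 8-heavy-atom methyl/hydroxyl-benzene core with the template at
    bit-identical coordinates.
    """
    if n_queries < 1:
        raise ValueError("n_queries must be >= 1")
    if n_queries > len(_SUBSTITUENTS) - 1:
        raise ValueError(f"at most {len(_SUBSTITUENTS) - 1} queries available")
    template_mol = _build_trisubstituted_benzene(*_SUBSTITUENTS[0])
    queries = []
    true_poses = []
    for el, bond in _SUBSTITUENTS[1 : n_queries + 1]:
        qmol = _build_trisubstituted_benzene(el, bond)
        lig = _as_standard_ligand(qmol)
        queries.append(lig)
        true_poses.append(Chem.Mol(lig.mol3d))
    return ToyComplex(
        seed=seed,
        receptor=_receptor_atoms(seed),
        template=_as_standard_ligand(template_mol),
        template_structure_id="TOYT0001",
        queries=queries,
        true_poses=true_poses,
    )


def toy_benchmark_entries(
    toy: ToyComplex,
    seed: int = 0,
    n_conformers: int = 5,
    include_queries_in_pool: bool = True,
    exact_copy_templates: bool = True,
    pocket_radius: float = 8.0,
):
    """Leave-one-out benchmark entries for the toy complex.

    Each entry's query is rebuilt from its SMILES with freshly generated
    conformers so the ground-truth pose cannot leak into the prediction; the
    crystal pose is kept separately as the truth reference.

    With ``exact_copy_templates`` the pool additionally holds each query's
    crystal pose under a second source id (``TOYCnn``) — the same ligand
    re-determined in another structure. Leave-one-out removes only the query's
    own complex (``TOYQnn``), so the exact copy remains the best available
    template, which is the self-recovery scenario.
    """
    from fragmint import chemprep
    from fragmint.templates import TemplateEntry, TemplatePool
    from fragmint.validation import BenchmarkEntry

    pocket = toy.pocket(pocket_radius)
    pool_entries = list(toy.template_pool(include_queries=include_queries_in_pool).entries)
    if exact_copy_templates:
        for i, q in enumerate(toy.queries):
            pool_entries.append(TemplateEntry(ligand=q, structure_id=f"TOYC{i:02d}"))
    pool = TemplatePool(protein_id="TOY00001", entries=pool_entries)
    entries = []
    for i, q in enumerate(toy.queries):
        fresh = chemprep.standardize_ligand(Chem.MolToSmiles(q.mol))
        chemprep.generate_conformers(fresh, n_requested=n_conformers, seed=seed + i)
        entries.append(
            BenchmarkEntry(
                entry_id=f"toy{i}",
                query=fresh,
                pool=pool,
                pocket=pocket,
                truth_mol=Chem.Mol(toy.true_poses[i]),
                self_structure_id=f"TOYQ{i:02d}" if include_queries_in_pool else None,
            )
        )
    return entries


def make_scored_dataset(
    planted_weights: ScoringWeights | None = None,
    n: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled pose-score table with a planted linear metric→success rule.

    Four metrics are drawn uniform on [0, 1]; the planted confidence score is
    their weighted sum; success is (cs > median cs), with Gaussian label noise
    of ``noise_sd`` added to the score before thresholding. Columns: sim2d,
    sim3d, dock_norm, int_sim_norm, cs_true, success.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    w = (planted_weights or ScoringWeights()).as_array()
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, 4))
    cs = X @ w
    noisy = cs + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    labels = noisy > np.median(cs)
    return pd.DataFrame(
        {
            "sim2d": X[:, 0],
            "sim3d": X[:, 1],
            "dock_norm": X[:, 2],
            "int_sim_norm": X[:, 3],
            "cs_true": cs,
            "success": labels,
        }
    )
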