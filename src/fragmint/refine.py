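"""Tethered local pose refinement inside a rigid protein pocket.

The refinement objective is MMFF94s ligand internal energy plus
Lennard-Jones/Coulomb ligand–pocket nonbonded terms plus harmonic tethers on
the query–template maximum common substructure, minimized with L-BFGS-B over
the ligand coordinates only (rigid receptor). This is a desk-scale functional
substitute for an external tethered-docking engine; an adapter seam
(:class:`TetheredDockingAdapter`) allows such a binary to be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS
from scipy.optimize import minimize

# amber-flavoured 12-6 parameters per element: (rmin/2 Å, epsilon kcal/mol)
_LJ_PARAMS = {
    1: (0.60, 0.016), 6: (1.908, 0.086), 7: (1.824, 0.170), 8: (1.661, 0.210),
    9: (1.75, 0.061), 15: (2.10, 0.200), 16: (2.00, 0.250), 17: (1.948, 0.265),
    35: (2.22, 0.320), 53: (2.35, 0.400),
}
_LJ_DEFAULT = (1.9, 0.1)

# formal-charge centers of ionizable side chains (residue, atom name) -> charge
_PROTEIN_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}

_ELEMENT_Z = {"C": 6, "N": 7, "O": 8, "S": 16, "H": 1, "P": 15}

# components stripped when building a pocket (waters, common ions, cryo additives)
_EXCLUDED_RESNAMES = {
    "HOH", "WAT", "DOD", "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE",
    "SO4", "PO4", "GOL", "EDO", "PEG", "DMS", "ACT", "NAG", "FMT",
}


@dataclass
class PocketModel:
    """Rigid protein environment around a binding site.

    Only polymer (amino-acid) heavy atoms are retained; waters, metal ions and
    non-polymeric cofactors are logged in ``excluded`` and dropped.
    """

    elements: np.ndarray  # atomic numbers
    coords: np.ndarray  # (N, 3) Å
    res_ids: np.ndarray  # residue sequence numbers
    res_names: np.ndarray
    chains: np.ndarray
    atom_names: np.ndarray
    center: np.ndarray
    radius: float
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def partial_charges(self) -> np.ndarray:
        q = np.zeros(len(self))
        for i, (rn, an) in enumerate(zip(self.res_names, self.atom_names)):
            q[i] = _PROTEIN_CHARGES.get((str(rn), str(an)), 0.0)
        return q

    def residue_labels(self) -> np.ndarray:
        """Per-atom 'RESNAME<resid>.<chain>' labels, e.g. 'HIS80.A'."""
        return np.array(
            [f"{rn}{ri}.{ch}" for rn, ri, ch in zip(self.res_names, self.res_ids, self.chains)]
        )


def load_structure(path: str | Path):
    """Read a PDB or mmCIF file into a biotite AtomArray (first model)."""
    import biotite.structure.io.pdb as pdb_io

    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        import biotite.structure.io.pdbx as pdbx_io

        f = pdbx_io.CIFFile.read(str(path))
        return pdbx_io.get_structure(f, model=1)
    f = pdb_io.PDBFile.read(str(path))
    return f.get_structure(model=1)


def pocket_from_structure(
    atoms,
    ligand_coords: np.ndarray,
    radius: float = 8.0,
) -> PocketModel:
    """Extract the pocket: polymer residues with any heavy atom within ``radius``
    Å of the reference ligand coordinates.
    """
    import biotite.structure as struc

    excluded = sorted(
        {str(r) for r in np.unique(atoms.res_name[~struc.filter_amino_acids(atoms)])}
    )
    poly = atoms[struc.filter_amino_acids(atoms)]
    poly = poly[poly.element != "H"]
    if len(poly) == 0:
        raise ValueError("no polymer atoms in structure")
    d = np.linalg.norm(poly.coord[:, None, :] - ligand_coords[None, :, :], axis=-1)
    near = d.min(axis=1) <= radius
    # keep whole residues
    res_keys = set(zip(poly.chain_id[near], poly.res_id[near]))
    keep = np.array([(c, r) in res_keys for c, r in zip(poly.chain_id, poly.res_id)])
    sel = poly[keep]
    if len(sel) == 0:
        raise ValueError("no pocket residues within radius")
    elements = np.array([_ELEMENT_Z.get(str(e).upper(), 6) for e in sel.element])
    return PocketModel(
        elements=elements,
        coords=np.asarray(sel.coord, dtype=float),
        res_ids=np.asarray(sel.res_id),
        res_names=np.asarray(sel.res_name),
        chains=np.asarray(sel.chain_id),
        atom_names=np.asarray(sel.atom_name),
        center=np.asarray(ligand_coords).mean(axis=0),
        radius=radius,
        excluded=[e for e in excluded if e in _EXCLUDED_RESNAMES or e not in _ELEMENT_Z],
    )


def load_pocket(path: str | Path, ligand_coords: np.ndarray, radius: float = 8.0) -> PocketModel:
    return pocket_from_structure(load_structure(path), ligand_coords, radius)


@dataclass
class TetherSpec:
    """Harmonic restraints holding MCS atoms near their aligned coordinates."""

    mapping: dict[int, int]  # query atom index -> template atom index
    reference: np.ndarray  # (n_mapped, 3) Å, ordered as sorted(mapping)
    force_constant: float = 10.0  # kcal/mol/Å²
    tolerance: float = 0.5  # Å

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("tether mapping must be injective")
        if len(self.reference) != len(self.mapping):
            raise ValueError("every mapped atom needs a reference coordinate")

    @property
    def query_indices(self) -> list[int]:
        return sorted(self.mapping)


def find_mcs(
    query: Chem.Mol, template: Chem.Mol, min_atoms: int = 3, timeout: int = 10
) -> dict[int, int] | None:
    """Connected maximum common substructure by element + bond order.

    Returns the query→template atom mapping of a maximum solution with a
    deterministic tie-break (lexicographically smallest substructure match on
    each side), or ``None`` when the MCS has fewer than ``min_atoms`` heavy
    atoms (no-tether outcome).
    """
    res = rdFMCS.FindMCS(
        [query, template],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=False,
        completeRingsOnly=False,
        timeout=timeout,
    )
    if res.canceled or res.numAtoms < min_atoms:
        return None
    patt = Chem.MolFromSmarts(res.smartsString)
    q_matches = query.GetSubstructMatches(patt, uniquify=True, maxMatches=512)
    t_matches = template.GetSubstructMatches(patt, uniquify=True, maxMatches=512)
    if not q_matches or not t_matches:
        return None
    q_match = min(q_matches)
    t_match = min(t_matches)
    return dict(zip(q_match, t_match))


def make_tether(
    pose_mol: Chem.Mol,
    mapping: dict[int, int],
    force_constant: float = 10.0,
    tolerance: float = 0.5,
) -> TetherSpec:
    """Tether spec whose references are the aligned pose's own MCS coordinates."""
    pos = np.asarray(pose_mol.GetConformer().GetPositions())
    ref = pos[sorted(mapping)]
    return TetherSpec(
        mapping=mapping, reference=ref, force_constant=force_constant, tolerance=tolerance
    )


class RefinementError(RuntimeError):
    pass


@dataclass
class RefinementResult:
    mol: Chem.Mol
    energy: float
    initial_energy: float
    clash_flag: bool
    tether_ok: bool
    flags: list[str] = field(default_factory=list)


def _pocket_energy_grad(
    lig_pos: np.ndarray,
    lig_z: np.ndarray,
    lig_q: np.ndarray,
    pocket: PocketModel,
    cutoff: float = 8.0,
) -> tuple[float, np.ndarray]:
    """LJ 12-6 + Coulomb (distance-dependent dielectric) energy and gradient."""
    delta = lig_pos[:, None, :] - pocket.coords[None, :, :]
    d2 = np.sum(delta**2, axis=-1)
    d2 = np.maximum(d2, 0.25)  # guard: softcore floor at 0.5 Å
    mask = d2 <= cutoff**2
    if not mask.any():
        return 0.0, np.zeros_like(lig_pos)
    rl = np.array([_LJ_PARAMS.get(int(z), _LJ_DEFAULT) for z in lig_z])
    rp = np.array([_LJ_PARAMS.get(int(z), _LJ_DEFAULT) for z in pocket.elements])
    rmin = rl[:, None, 0] + rp[None, :, 0]
    eps = np.sqrt(rl[:, None, 1] * rp[None, :, 1])
    inv_d2 = 1.0 / d2
    s2 = rmin**2 * inv_d2
    s6 = s2**3
    e_lj = eps * (s6 * s6 - 2.0 * s6)
    # dE/dd2 for LJ
    dlj_dd2 = eps * (-6.0 * s6 * s6 + 6.0 * s6) * inv_d2
    pq = pocket.partial_charges
    qq = 332.06 * lig_q[:, None] * pq[None, :]
    e_coul = qq * inv_d2  # epsilon(r) = r distance-dependent dielectric
    dcoul_dd2 = -qq * inv_d2**2
    e = float((e_lj + e_coul)[mask].sum())
    coef = np.where(mask, 2.0 * (dlj_dd2 + dcoul_dd2), 0.0)
    grad = np.einsum("ij,ijk->ik", coef, delta)
    return e, grad


def min_protein_distance(lig_pos: np.ndarray, lig_z: np.ndarray, pocket: PocketModel) -> float:
    heavy = lig_pos[lig_z > 1]
    if len(heavy) == 0 or len(pocket) == 0:
        return np.inf
    d = np.linalg.norm(heavy[:, None, :] - pocket.coords[None, :, :], axis=-1)
    return float(d.min())


def tethered_minimize(
    pose_mol: Chem.Mol,
    pocket: PocketModel | None,
    tether: TetherSpec | None,
    clash_floor: float = 2.0,
    maxiter: int = 300,
) -> RefinementResult:
    """Minimize ligand MMFF94s + pocket nonbonded + harmonic tether energy.

    The protein is rigid: its coordinates are never touched. Raises
    :class:`RefinementError` if the optimizer diverges to non-finite energy.
    """
    mol = Chem.Mol(pose_mol)
    if mol.GetNumConformers() == 0:
        raise ValueError("pose has no coordinates")
    needs_h = all(a.GetAtomicNum() > 1 for a in mol.GetAtoms()) and mol.GetNumAtoms() > 1
    if needs_h:
        mol = Chem.AddHs(mol, addCoords=True)
    conf = mol.GetConformer()
    x0 = np.asarray(conf.GetPositions()).ravel()
    lig_z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])

    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
    ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=0) if props else None

    qmol = Chem.Mol(mol)
    try:
        AllChem.ComputeGasteigerCharges(qmol)
        lig_q = np.array(
            [float(a.GetDoubleProp("_GasteigerCharge")) for a in qmol.GetAtoms()]
        )
        lig_q[~np.isfinite(lig_q)] = 0.0
    except Exception:
        lig_q = np.zeros(mol.GetNumAtoms())

    tether_idx = np.array(tether.query_indices, dtype=int) if tether else np.empty(0, int)
    tether_ref = tether.reference if tether else None
    k_tether = tether.force_constant if tether else 0.0

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        pos = x.reshape(-1, 3)
        e = 0.0
        grad = np.zeros_like(pos)
        if ff is not None:
            e += ff.CalcEnergy(x.tolist())
            grad += np.asarray(ff.CalcGrad(x.tolist())).reshape(-1, 3)
        if pocket is not None and len(pocket) > 0:
            ep, gp = _pocket_energy_grad(pos, lig_z, lig_q, pocket)
            e += ep
            grad += gp
        if k_tether > 0 and len(tether_idx) > 0:
            dr = pos[tether_idx] - tether_ref
            e += k_tether * float(np.sum(dr**2))
            grad[tether_idx] += 2.0 * k_tether * dr
        return e, grad.ravel()

    e0, _ = objective(x0)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise RefinementError(f"divergent minimization (energy {res.fun})")
    # keep the better of start and optimizer end: objective never increases
    if res.fun <= e0:
        x_final, e_final = res.x, float(res.fun)
    else:  # pragma: no cover - L-BFGS-B line search guarantees descent
        x_final, e_final = x0, float(e0)
    pos = x_final.reshape(-1, 3)
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, p.tolist())

    flags = []
    clash = False
    if pocket is not None and len(pocket) > 0:
        if min_protein_distance(pos, lig_z, pocket) < clash_floor:
            clash = True
            flags.append("clash")
    tether_ok = True
    if tether is not None and len(tether_idx) > 0:
        disp = np.linalg.norm(pos[tether_idx] - tether_ref, axis=1)
        tether_ok = bool(disp.max() <= tether.tolerance)
        if not tether_ok:
            flags.append("tether_exceeded")
    if needs_h:
        mol = Chem.RemoveHs(mol)
    return RefinementResult(
        mol=mol,
        energy=e_final,
        initial_energy=float(e0),
        clash_flag=clash,
        tether_ok=tether_ok,
        flags=flags,
    )


class TetheredDockingAdapter(Protocol):
    """Seam for substituting an external tethered-docking binary."""

    def __call__(
        self, pose_mol: Chem.Mol, pocket: PocketModel, tether: TetherSpec | None
    ) -> RefinementResult: ...
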