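"""Interaction fingerprints, bioisostere search, and scaffold hopping.

An interaction fingerprint is the set of (residue, type) contacts a posed
molecule makes, with type one of hydrogen-bond donor/acceptor (from the
ligand's perspective), π-stacking, hydrophobic, ionic, and halogen bond.
Detection is purely geometric with documented, config-exposed thresholds.
Bioisostere search returns repository fragments replicating a reference
fingerprint; scaffold hopping returns fragments that occupy a reference core's
volume and offer an attachment point compatible with every exit vector of the
core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from rdkit import Chem

from fragmint.field_align import GaussianCloud, atom_alpha, gaussian_cloud, shape_tanimoto, VDW_RADII
from fragmint.fragmenter import FragmentPose
from fragmint.library import FragmentEnvironmentPair
from fragmint.refine import PocketModel

INTERACTION_TYPES = ("HBDonor", "HBAcceptor", "PiStacking", "Hydrophobic", "Ionic", "Halogen")


@dataclass
class GeometryConfig:
    """Geometric interaction-detection thresholds (distances Å, angles degrees)."""

    hbond_distance: float = 3.5  # donor–acceptor heavy-atom distance
    hbond_angle: float = 130.0  # minimum D–H···A angle when the H is resolved
    pi_distance: float = 5.5  # ring centroid–centroid
    pi_parallel_angle: float = 30.0  # max inter-plane angle, parallel stacking
    pi_tshape_range: tuple[float, float] = (60.0, 90.0)
    hydrophobic_distance: float = 4.5
    ionic_distance: float = 4.5
    halogen_distance: float = 3.5


# protein-side chemistry tables (heavy atoms only; PDB files carry no H)
_PROT_DONOR_ATOMS = {
    ("*", "N"),  # backbone amide N (not proline, ignored at this scale)
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"), ("CYS", "SG"),
}
_PROT_ACCEPTOR_ATOMS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}
_PROT_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
_PROT_CHARGED = {
    ("ASP", "OD1"): -1, ("ASP", "OD2"): -1, ("GLU", "OE1"): -1, ("GLU", "OE2"): -1,
    ("LYS", "NZ"): 1, ("ARG", "NH1"): 1, ("ARG", "NH2"): 1, ("ARG", "CZ"): 1,
}


def _prot_flag(table: set, res_name: str, atom_name: str) -> bool:
    return ("*", atom_name) in table or (res_name, atom_name) in table


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[-1]


def _protein_rings(pocket: PocketModel):
    """(residue label, centroid, normal) for each complete aromatic side chain."""
    labels = pocket.residue_labels()
    rings = []
    for label in np.unique(labels):
        idx = np.nonzero(labels == label)[0]
        res_name = str(pocket.res_names[idx[0]])
        wanted = _PROT_RING_ATOMS.get(res_name)
        if wanted is None:
            continue
        name_of = {str(pocket.atom_names[i]): i for i in idx}
        if not all(a in name_of for a in wanted):
            continue
        coords = pocket.coords[[name_of[a] for a in wanted]]
        rings.append((label, coords.mean(axis=0), _ring_normal(coords)))
    return rings


def _ligand_rings(mol: Chem.Mol, pos: np.ndarray):
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            coords = pos[list(ring)]
            rings.append((coords.mean(axis=0), _ring_normal(coords)))
    return rings


def interaction_fingerprint(
    pose_mol: Chem.Mol,
    pocket: PocketModel,
    geometry: GeometryConfig | None = None,
) -> frozenset[tuple[str, str]]:
    """Set of (residue label, interaction type) contacts of a posed molecule.

    Hydrogen-bond typing is from the ligand's point of view: ``HBDonor`` means
    the ligand donates. The D–H···A angle criterion applies when the donor's
    hydrogens carry coordinates; protein donors (no hydrogens in the model) use
    the distance criterion alone.
    """
    geo = geometry or GeometryConfig()
    pos = np.asarray(pose_mol.GetConformer().GetPositions())
    labels = pocket.residue_labels()
    out: set[tuple[str, str]] = set()

    prot_don = np.array(
        [
            _prot_flag(_PROT_DONOR_ATOMS, str(rn), str(an))
            for rn, an in zip(pocket.res_names, pocket.atom_names)
        ]
    )
    prot_acc = np.array(
        [
            _prot_flag(_PROT_ACCEPTOR_ATOMS, str(rn), str(an))
            for rn, an in zip(pocket.res_names, pocket.atom_names)
        ]
    )
    prot_q = np.array(
        [_PROT_CHARGED.get((str(rn), str(an)), 0) for rn, an in zip(pocket.res_names, pocket.atom_names)]
    )
    prot_c = pocket.elements == 6

    for atom in pose_mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z <= 1:
            continue
        i = atom.GetIdx()
        d = np.linalg.norm(pocket.coords - pos[i], axis=1)

        # ligand donor -> protein acceptor
        if z in (7, 8, 16) and atom.GetTotalNumHs(includeNeighbors=True) > 0:
            h_pos = [
                pos[n.GetIdx()] for n in atom.GetNeighbors() if n.GetAtomicNum() == 1
            ]
            for j in np.nonzero(prot_acc & (d <= geo.hbond_distance))[0]:
                if h_pos:
                    ok = False
                    for hp in h_pos:
                        v1 = pos[i] - hp
                        v2 = pocket.coords[j] - hp
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= geo.hbond_angle:
                            ok = True
                            break
                    if not ok:
                        continue
                out.add((str(labels[j]), "HBDonor"))

        # ligand acceptor <- protein donor (distance-only: protein H unresolved)
        if z in (7, 8):
            for j in np.nonzero(prot_don & (d <= geo.hbond_distance))[0]:
                out.add((str(labels[j]), "HBAcceptor"))

        # hydrophobic: apolar carbon / halogen against protein carbon
        neighbors_z = {n.GetAtomicNum() for n in atom.GetNeighbors()}
        apolar = (z == 6 and not neighbors_z & {7, 8}) or z in (9, 17, 35, 53)
        if apolar:
            for j in np.nonzero(prot_c & (d <= geo.hydrophobic_distance))[0]:
                out.add((str(labels[j]), "Hydrophobic"))

        # ionic: opposite formal charges
        q = atom.GetFormalCharge()
        if q != 0:
            for j in np.nonzero((prot_q * q < 0) & (d <= geo.ionic_distance))[0]:
                out.add((str(labels[j]), "Ionic"))

        # halogen bond: ligand X against protein acceptor
        if z in (17, 35, 53):
            for j in np.nonzero(prot_acc & (d <= geo.halogen_distance))[0]:
                out.add((str(labels[j]), "Halogen"))

    # π-stacking between complete aromatic rings
    prot_rings = _protein_rings(pocket)
    for centroid, normal in _ligand_rings(pose_mol, pos):
        for label, p_centroid, p_normal in prot_rings:
            if np.linalg.norm(centroid - p_centroid) > geo.pi_distance:
                continue
            cosang = abs(float(normal @ p_normal))
            ang = np.degrees(np.arccos(np.clip(cosang, 0, 1)))
            lo, hi = geo.pi_tshape_range
            if ang <= geo.pi_parallel_angle or lo <= ang <= hi:
                out.add((label, "PiStacking"))
    return frozenset(out)


def fingerprint_to_csv(fp: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(sorted(fp), columns=["residue", "type"]).to_csv(path, index=False)


def fingerprint_from_csv(path) -> frozenset[tuple[str, str]]:
    """Ingest an externally computed fingerprint for cross-checking."""
    df = pd.read_csv(path)
    return frozenset(zip(df["residue"].astype(str), df["type"].astype(str)))


def _pair_best_cs(pair: FragmentEnvironmentPair) -> float:
    vals = [p["cs"] for p in pair.provenance if p.get("cs") is not None]
    return max(vals) if vals else -np.inf


def bioisostere_search(
    pairs: list[FragmentEnvironmentPair],
    protein_id: str,
    reference: frozenset[tuple[str, str]],
    mode: Literal["strict", "superset"] = "strict",
) -> list[FragmentEnvironmentPair]:
    """Fragments replicating a reference interaction fingerprint.

    ``strict``: the fragment's fingerprint restricted to the reference's
    residues equals the reference exactly. ``superset``: the fragment makes at
    least all reference interactions. Results sorted by best parent confidence
    score descending. An empty result with no matching protein is valid.
    """
    ref_residues = {r for r, _ in reference}
    hits = []
    for pair in pairs:
        if pair.protein_id != protein_id or pair.fingerprint is None:
            continue
        fp = pair.fingerprint
        if mode == "strict":
            restricted = frozenset(x for x in fp if x[0] in ref_residues)
            if restricted == reference:
                hits.append(pair)
        elif mode == "superset":
            if reference <= fp:
                hits.append(pair)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    hits.sort(key=lambda p: (-_pair_best_cs(p), p.fragment_key))
    return hits


@dataclass
class AttachmentVector:
    """Anchored outward direction of a bond crossing a core boundary."""

    anchor: np.ndarray  # (3,) Å, core-side atom position
    direction: np.ndarray  # unit vector pointing out of the core
    core_atom: int | None = None
    outside_atom: int | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, float)
        self.direction = np.asarray(self.direction, float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-6:
            if n < 1e-9:
                raise ValueError("zero-length attachment direction")
            self.direction = self.direction / n


def extract_attachment_vectors(
    pose_mol: Chem.Mol, core_atoms: Iterable[int]
) -> list[AttachmentVector]:
    """One vector per bond crossing the core boundary, pointing outward.

    Raises if the core selection is not a connected substructure.
    """
    core = set(core_atoms)
    if not core:
        raise ValueError("empty core selection")
    # connectivity check by flood fill over core-internal bonds
    seen = {min(core)}
    stack = [min(core)]
    while stack:
        a = stack.pop()
        for n in pose_mol.GetAtomWithIdx(a).GetNeighbors():
            j = n.GetIdx()
            if j in core and j not in seen:
                seen.add(j)
                stack.append(j)
    if seen != core:
        raise ValueError("core selection is not connected")
    pos = np.asarray(pose_mol.GetConformer().GetPositions())
    vectors = []
    for bond in pose_mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in core) == (b in core):
            continue
        inside, outside = (a, b) if a in core else (b, a)
        if pose_mol.GetAtomWithIdx(outside).GetAtomicNum() <= 1:
            continue  # H caps are not substituents
        vec = pos[outside] - pos[inside]
        vectors.append(
            AttachmentVector(
                anchor=pos[inside],
                direction=vec / np.linalg.norm(vec),
                core_atom=inside,
                outside_atom=outside,
            )
        )
    return vectors


def _core_cloud(pose_mol: Chem.Mol, core_atoms: set[int]) -> GaussianCloud:
    pos = np.asarray(pose_mol.GetConformer().GetPositions())
    coords, alphas = [], []
    for i in sorted(core_atoms):
        atom = pose_mol.GetAtomWithIdx(i)
        if atom.GetAtomicNum() <= 1:
            continue
        coords.append(pos[i])
        alphas.append(atom_alpha(VDW_RADII.get(atom.GetAtomicNum(), 1.7)))
    return GaussianCloud(
        coords=np.asarray(coords), alphas=np.asarray(alphas), charges=np.zeros(len(coords))
    )


@dataclass
class ScaffoldHopHit:
    pair: FragmentEnvironmentPair
    shape_overlap: float
    n_vectors_matched: int
    vector_deviation: float  # mean anchor distance (Å) over matched vectors


def scaffold_hop(
    pairs: list[FragmentEnvironmentPair],
    protein_id: str,
    reference_mol: Chem.Mol,
    core_atoms: Iterable[int],
    anchor_tolerance: float = 1.0,
    angle_tolerance: float = 30.0,
    min_shape_overlap: float = 0.5,
) -> list[ScaffoldHopHit]:
    """Alternative cores: fragments overlapping the reference core's volume that
    offer a compatible attachment point for every reference exit vector.

    Candidates are ranked by (vectors matched desc, shape overlap desc, parent
    confidence desc).
    """
    core = set(core_atoms)
    ref_vectors = extract_attachment_vectors(reference_mol, core)
    if not ref_vectors:
        raise ValueError("reference core has no attachment vectors")
    core_cloud = _core_cloud(reference_mol, core)
    cos_tol = np.cos(np.radians(angle_tolerance))

    hits = []
    for pair in pairs:
        if pair.protein_id != protein_id or pair.representative is None:
            continue
        frag: FragmentPose = pair.representative
        frag_cloud = gaussian_cloud(frag.mol)
        overlap = shape_tanimoto(frag_cloud, core_cloud)
        if overlap < min_shape_overlap:
            continue
        cand = [(np.asarray(a), np.asarray(d)) for a, d in frag.attachments]
        matched = 0
        deviations = []
        for rv in ref_vectors:
            best = None
            for anchor, direction in cand:
                dist = float(np.linalg.norm(anchor - rv.anchor))
                if dist > anchor_tolerance:
                    continue
                if float(direction @ rv.direction) < cos_tol:
                    continue
                if best is None or dist < best:
                    best = dist
            if best is not None:
                matched += 1
                deviations.append(best)
        if matched < len(ref_vectors):
            continue
        hits.append(
            ScaffoldHopHit(
                pair=pair,
                shape_overlap=float(overlap),
                n_vectors_matched=matched,
                vector_deviation=float(np.mean(deviations)) if deviations else 0.0,
            )
        )
    hits.sort(
        key=lambda h: (-h.n_vectors_matched, -h.shape_overlap, -_pair_best_cs(h.pair))
    )
    return hits


def assemble_molecule(
    reference_mol: Chem.Mol,
    core_atoms: Iterable[int],
    candidate: FragmentPose,
    relax: bool = True,
) -> Chem.Mol | None:
    """Naively fuse the reference's peripheral groups onto a candidate core.

    Each peripheral substituent of the reference is bonded to the candidate
    attachment anchor nearest its original exit vector; a final force-field
    relaxation of the assembled molecule alone follows. No synthetic
    feasibility is implied. Returns None when fusion fails chemistry checks.
    """
    from rdkit.Chem import AllChem

    core = set(core_atoms)
    ref_vectors = extract_attachment_vectors(reference_mol, core)
    frag = Chem.Mol(candidate.mol)
    cand_vecs = [(np.asarray(a), np.asarray(d)) for a, d in candidate.attachments]
    if not cand_vecs or not ref_vectors:
        return None
    frag_pos = np.asarray(frag.GetConformer().GetPositions())

    combined = Chem.RWMol(frag)
    ref_pos = np.asarray(reference_mol.GetConformer().GetPositions())
    for rv in ref_vectors:
        # peripheral atoms reachable from the outside atom without re-entering core
        peri = set()
        stack = [rv.outside_atom]
        while stack:
            a = stack.pop()
            if a in peri or a in core:
                continue
            peri.add(a)
            for n in reference_mol.GetAtomWithIdx(a).GetNeighbors():
                stack.append(n.GetIdx())
        # nearest candidate anchor atom
        dists = [np.linalg.norm(a - rv.anchor) for a, _ in cand_vecs]
        anchor_xyz = cand_vecs[int(np.argmin(dists))][0]
        anchor_idx = int(
            np.argmin(np.linalg.norm(frag_pos - anchor_xyz, axis=1))
        )
        index_map = {}
        for a in sorted(peri):
            atom = reference_mol.GetAtomWithIdx(a)
            new_idx = combined.AddAtom(Chem.Atom(atom.GetAtomicNum()))
            index_map[a] = new_idx
        conf = combined.GetConformer()
        for a, new_idx in index_map.items():
            conf.SetAtomPosition(new_idx, ref_pos[a].tolist())
        for bond in reference_mol.GetBonds():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if a in index_map and b in index_map:
                combined.AddBond(index_map[a], index_map[b], bond.GetBondType())
        anchor_atom = combined.GetAtomWithIdx(anchor_idx)
        if anchor_atom.GetNumExplicitHs() > 0:
            anchor_atom.SetNumExplicitHs(anchor_atom.GetNumExplicitHs() - 1)
        combined.AddBond(anchor_idx, index_map[rv.outside_atom], Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if relax:
        try:
            molh = Chem.AddHs(mol, addCoords=True)
            AllChem.MMFFOptimizeMolecule(molh, mmffVariant="MMFF94s", maxIters=200)
            mol = Chem.RemoveHs(molh)
        except Exception:
            pass
    return mol


def write_query_results(hits: list, path) -> None:
    """CSV of fragment key, protein, best parent CS, and per-hit scores."""
    rows = []
    for h in hits:
        if isinstance(h, ScaffoldHopHit):
            rows.append(
                {
                    "fragment_key": h.pair.fragment_key,
                    "protein_id": h.pair.protein_id,
                    "best_cs": _pair_best_cs(h.pair),
                    "shape_overlap": h.shape_overlap,
                    "n_vectors_matched": h.n_vectors_matched,
                    "vector_deviation": h.vector_deviation,
                }
            )
        else:
            rows.append(
                {
                    "fragment_key": h.fragment_key,
                    "protein_id": h.protein_id,
                    "best_cs": _pair_best_cs(h),
                    "interactions": ";".join(f"{r}:{t}" for r, t in sorted(h.fingerprint or ())),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
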