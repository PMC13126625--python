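"""Gaussian molecular-field similarity and rigid + conformational superposition.

Each heavy atom contributes a spherical Gaussian. The steric channel uses the
Grant–Pickup density (amplitude 2.7, width set so the Gaussian integrates to
the atom's van der Waals volume); the electrostatic channel reuses the same
centers and widths with Gasteiger partial charges as amplitudes. Similarity is
the Carbo cosine O(a,b)/sqrt(O(a,a)·O(b,b)) per channel, mixed 50/50 by
default. Alignment maximizes the mixed similarity over rotations and
translations from 12 deterministic starts (principal-axes alignments) plus
seeded random starts, independently for every query conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

# Bondi van der Waals radii (Å); fallback 1.7 for untabulated elements.
VDW_RADII = {
    1: 1.20, 5: 1.92, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 14: 2.10,
    15: 1.80, 16: 1.80, 17: 1.75, 35: 1.85, 53: 1.98,
}

_STERIC_AMPLITUDE = 2.7  # Grant & Pickup hard-sphere-matching amplitude


@dataclass
class FieldModel:
    """Parameters of the two-channel Gaussian field.

    ``electrostatic_weight`` mixes the channels:
    ``sim = (1 - w) * steric + w * electrostatic``. The electrostatic cosine
    can be negative for opposed charge patterns; the mixed similarity is
    clamped to [0, 1].
    """

    electrostatic_weight: float = 0.5
    amplitude: float = _STERIC_AMPLITUDE
    radius_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.electrostatic_weight <= 1.0:
            raise ValueError("electrostatic_weight must be in [0, 1]")
        if self.radius_scale <= 0:
            raise ValueError("radius_scale must be > 0")


@dataclass
class GaussianCloud:
    """Per-atom Gaussian parameters for one posed molecule (heavy atoms only)."""

    coords: np.ndarray  # (N, 3) Å
    alphas: np.ndarray  # (N,) Å^-2, all > 0
    charges: np.ndarray  # (N,) Gasteiger partial charges


def atom_alpha(radius: float, amplitude: float = _STERIC_AMPLITUDE) -> float:
    """Gaussian exponent giving the atom its van der Waals volume at this amplitude."""
    return float(np.pi * (3.0 * amplitude / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0))


def gaussian_cloud(
    mol: Chem.Mol, conf_id: int = 0, model: FieldModel | None = None
) -> GaussianCloud:
    """Extract heavy-atom Gaussian parameters from a posed molecule."""
    model = model or FieldModel()
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D coordinates")
    mol = Chem.Mol(mol)
    try:
        AllChem.ComputeGasteigerCharges(mol)
        charges_all = [float(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    except Exception:
        charges_all = [0.0] * mol.GetNumAtoms()
    charges_all = [0.0 if not np.isfinite(q) else q for q in charges_all]
    pos = np.asarray(mol.GetConformer(conf_id).GetPositions())
    coords, alphas, charges = [], [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        r = VDW_RADII.get(atom.GetAtomicNum(), 1.7) * model.radius_scale
        coords.append(pos[atom.GetIdx()])
        alphas.append(atom_alpha(r, model.amplitude))
        charges.append(charges_all[atom.GetIdx()])
    if not coords:
        raise ValueError("no heavy atoms")
    return GaussianCloud(
        coords=np.asarray(coords), alphas=np.asarray(alphas), charges=np.asarray(charges)
    )


def _overlap_matrix(a: GaussianCloud, b: GaussianCloud, coords_a=None) -> np.ndarray:
    """Pairwise Gaussian overlap integrals (unit amplitudes)."""
    ca = a.coords if coords_a is None else coords_a
    d2 = np.sum((ca[:, None, :] - b.coords[None, :, :]) ** 2, axis=-1)
    asum = a.alphas[:, None] + b.alphas[None, :]
    prod = a.alphas[:, None] * b.alphas[None, :]
    return (np.pi / asum) ** 1.5 * np.exp(-prod / asum * d2)


def channel_overlaps(
    a: GaussianCloud, b: GaussianCloud, coords_a=None, amplitude: float = _STERIC_AMPLITUDE
) -> tuple[float, float]:
    """(steric, electrostatic) total overlap integrals between two clouds."""
    m = _overlap_matrix(a, b, coords_a)
    steric = amplitude * amplitude * float(m.sum())
    elec = float(a.charges @ m @ b.charges)
    return steric, elec


def field_similarity(
    a: Chem.Mol | GaussianCloud,
    b: Chem.Mol | GaussianCloud,
    model: FieldModel | None = None,
    conf_id_a: int = 0,
    conf_id_b: int = 0,
) -> float:
    """Mixed-channel Carbo cosine similarity of two posed molecules, in [0, 1]."""
    model = model or FieldModel()
    ca = a if isinstance(a, GaussianCloud) else gaussian_cloud(a, conf_id_a, model)
    cb = b if isinstance(b, GaussianCloud) else gaussian_cloud(b, conf_id_b, model)
    return _similarity_from_clouds(ca, cb, model)


def _similarity_from_clouds(
    ca: GaussianCloud, cb: GaussianCloud, model: FieldModel, coords_a=None
) -> float:
    st_ab, el_ab = channel_overlaps(ca, cb, coords_a, model.amplitude)
    # self-overlaps are invariant under the rigid transform of coords_a
    st_aa, el_aa = channel_overlaps(ca, ca, amplitude=model.amplitude)
    st_bb, el_bb = channel_overlaps(cb, cb, amplitude=model.amplitude)
    if st_aa <= 0 or st_bb <= 0:
        raise ValueError("zero steric self-overlap")
    steric = st_ab / np.sqrt(st_aa * st_bb)
    w = model.electrostatic_weight
    if el_aa > 1e-12 and el_bb > 1e-12:
        elec = el_ab / np.sqrt(el_aa * el_bb)
    else:  # apolar molecule: electrostatic channel undefined, fall back to steric
        elec = steric
    return float(np.clip((1.0 - w) * steric + w * elec, 0.0, 1.0))


def shape_tanimoto(a: GaussianCloud, b: GaussianCloud) -> float:
    """Steric-channel Gaussian Tanimoto O_ab / (O_aa + O_bb − O_ab), no optimization."""
    o_ab, _ = channel_overlaps(a, b)
    o_aa, _ = channel_overlaps(a, a)
    o_bb, _ = channel_overlaps(b, b)
    return float(o_ab / (o_aa + o_bb - o_ab))


@dataclass
class AlignedPose:
    """One rigid superposition of a query conformer onto a template pose."""

    conformer_id: int
    rotation: np.ndarray  # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,) Å
    mol: Chem.Mol  # H-explicit copy, single conformer at the aligned coordinates
    similarity3d: float
    template_id: str | None = None
    sim2d: float | None = None
    flags: list[str] = dc_field(default_factory=list)

    def heavy_coords(self) -> np.ndarray:
        pos = np.asarray(self.mol.GetConformer().GetPositions())
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        return pos[idx]


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axes = vt
    if axes.shape[0] < 3:  # planar/linear degenerate: pad with orthogonal axes
        axes = np.vstack([axes, np.eye(3)])[:3]
        q, _ = np.linalg.qr(axes.T)
        axes = q.T
    if np.linalg.det(axes) < 0:
        axes[2] *= -1.0
    return axes


def _deterministic_starts(q_coords: np.ndarray, t_coords: np.ndarray) -> list[np.ndarray]:
    """12 proper rotations: 4 principal-axes sign matches × 3 axis permutations."""
    qa, ta = _principal_axes(q_coords), _principal_axes(t_coords)
    starts = []
    perms = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    for perm in perms:
        qa_p = qa[list(perm)]
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            signs = np.diag([sx, sy, sx * sy])  # det +1 always
            starts.append(ta.T @ signs @ qa_p)
    return starts


def align_to_template(
    query,
    template_mol: Chem.Mol,
    model: FieldModel | None = None,
    n_poses: int = 3,
    template_conf_id: int = 0,
    n_random_starts: int = 4,
    seed: int = 0,
    distinct_rmsd: float = 0.5,
    template_id: str | None = None,
) -> list[AlignedPose]:
    """Superpose every query conformer onto a template pose, return the best poses.

    Parameters
    ----------
    query:
        A ``StandardLigand`` with a populated conformer ensemble.
    template_mol:
        Posed template molecule (the crystal pose).
    n_poses:
        Number of distinct poses returned (pairwise heavy-atom RMSD ≥ 0.5 Å),
        sorted by similarity descending.
    """
    model = model or FieldModel()
    if query.mol3d is None or query.mol3d.GetNumConformers() == 0:
        raise ValueError("query has no conformers")
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    t_cloud = gaussian_cloud(template_mol, template_conf_id, model)
    t_centroid = t_cloud.coords.mean(axis=0)

    candidates: list[tuple[float, int, np.ndarray, np.ndarray]] = []
    for cid in range(query.mol3d.GetNumConformers()):
        q_cloud = gaussian_cloud(query.mol3d, cid, model)
        q_centroid = q_cloud.coords.mean(axis=0)
        q_centered = q_cloud.coords - q_centroid

        def objective(x, q_cloud=q_cloud, q_centered=q_centered):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            coords = q_centered @ rot.T + t_centroid + x[3:]
            return -_similarity_from_clouds(q_cloud, t_cloud, model, coords_a=coords)

        rot_starts = _deterministic_starts(q_cloud.coords, t_cloud.coords)
        for _ in range(n_random_starts):
            rot_starts.append(Rotation.random(random_state=rng).as_matrix())
        for rot0 in rot_starts:
            x0 = np.concatenate([Rotation.from_matrix(rot0).as_rotvec(), np.zeros(3)])
            res = minimize(objective, x0, method="L-BFGS-B", options={"maxiter": 120})
            rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
            trans = t_centroid + res.x[3:] - rot @ q_centroid
            candidates.append((-res.fun, cid, rot, trans))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    poses: list[AlignedPose] = []
    heavy_idx = [a.GetIdx() for a in query.mol3d.GetAtoms() if a.GetAtomicNum() > 1]
    for sim, cid, rot, trans in candidates:
        all_pos = np.asarray(query.mol3d.GetConformer(cid).GetPositions())
        new_pos = all_pos @ rot.T + trans
        heavy = new_pos[heavy_idx]
        distinct = all(
            np.sqrt(np.mean(np.sum((heavy - p.heavy_coords()) ** 2, axis=1))) >= distinct_rmsd
            for p in poses
        )
        if not distinct:
            continue
        mol = Chem.Mol(query.mol3d)
        mol.RemoveAllConformers()
        conf = Chem.Conformer(query.mol3d.GetConformer(cid))
        for i, p in enumerate(new_pos):
            conf.SetAtomPosition(i, p.tolist())
        mol.AddConformer(conf, assignId=True)
        poses.append(
            AlignedPose(
                conformer_id=cid,
                rotation=rot,
                translation=trans,
                mol=mol,
                similarity3d=float(sim),
                template_id=template_id,
            )
        )
        if len(poses) >= n_poses:
            break
    return poses


def write_poses_sdf(poses: list[AlignedPose], path) -> None:
    """Write aligned poses with template id, conformer id, similarity and transform tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = Chem.Mol(pose.mol)
            mol.SetProp("template_id", str(pose.template_id))
            mol.SetProp("conformer_id", str(pose.conformer_id))
            mol.SetProp("similarity3d", f"{pose.similarity3d:.6f}")
            mol.SetProp(
                "transform",
                ";".join(f"{v:.6f}" for v in np.concatenate([pose.rotation.ravel(), pose.translation])),
            )
            writer.write(mol)
    finally:
        writer.close()
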