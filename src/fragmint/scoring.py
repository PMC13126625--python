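"""The four pose metrics and their fusion into the confidence score.

CS = α·2Dsim + β·3Dsim + γ·IntDock + δ·IntSim with all four metrics
normalized to [0, 1]. IntDock is a score-only evaluation of the published
empirical docking terms (two attractive Gaussians, repulsion, hydrophobic,
hydrogen bond, rotor penalty) against the rigid pocket; IntSim is an estimated
affinity from typed protein–ligand atom-pair contact counts. Fusion weights
default to the grid-search optimum (0.027, 0.324, 0.378, 0.270) and
``optimize_weights`` reproduces that search: an exhaustive weight grid scored
by the best-threshold F1 for classifying successful poses (RMSD < 2 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from fragmint.config import PipelineConfig, ScoringWeights
from fragmint.refine import PocketModel

# ---------------------------------------------------------------------------
# IntDock: score-only empirical docking terms (published AutoDock Vina weights)
# ---------------------------------------------------------------------------

_XS_RADII = {6: 1.9, 7: 1.8, 8: 1.7, 9: 1.5, 15: 2.1, 16: 2.0, 17: 1.8, 35: 2.0, 53: 2.2}
_TERM_WEIGHTS = {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439,
}
_ROTOR_WEIGHT = 0.05846
_INTERACTION_CUTOFF = 8.0  # Å

_POLAR_PROTEIN_ELEMENTS = {7, 8}


@dataclass
class DockScore:
    """Raw score plus the per-term breakdown (pre-weight term sums)."""

    value: float
    terms: dict[str, float]
    n_rotors: int
    no_contact: bool = False


def _ligand_vina_types(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(hydrophobic, donor, acceptor, radii) per heavy atom of the ligand."""
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    hydro, don, acc, rad = [], [], [], []
    for a in heavy:
        z = a.GetAtomicNum()
        neighbors_z = {n.GetAtomicNum() for n in a.GetNeighbors()}
        is_hydro = (z == 6 and not neighbors_z & {7, 8}) or z in (9, 17, 35, 53)
        is_don = z in (7, 8) and a.GetTotalNumHs(includeNeighbors=True) > 0
        is_acc = z in (7, 8)
        hydro.append(is_hydro)
        don.append(is_don)
        acc.append(is_acc)
        rad.append(_XS_RADII.get(z, 1.9))
    return (np.array(hydro), np.array(don), np.array(acc), np.array(rad))


def _protein_vina_types(pocket: PocketModel):
    z = pocket.elements
    hydro = (z == 6) | (z == 16)
    don = z == 7  # backbone/side-chain N treated as donors; O of Ser/Thr/Tyr too
    name = np.char.array(pocket.atom_names.astype(str))
    resn = np.char.array(pocket.res_names.astype(str))
    hydroxyl = ((resn == "SER") | (resn == "THR") | (resn == "TYR")) & (
        (name == "OG") | (name == "OG1") | (name == "OH")
    )
    don = don | hydroxyl
    acc = z == 8
    acc = acc | (z == 7)  # aromatic/backbone N may accept; coarse typing
    rad = np.array([_XS_RADII.get(int(zz), 1.9) for zz in z])
    return hydro, don, acc, rad


def vina_terms(surface_dist: np.ndarray) -> dict[str, np.ndarray]:
    """The distance-dependent empirical terms on surface distance d (Å)."""
    d = surface_dist
    return {
        "gauss1": np.exp(-((d / 0.5) ** 2)),
        "gauss2": np.exp(-(((d - 3.0) / 2.0) ** 2)),
        "repulsion": np.where(d < 0, d**2, 0.0),
        "hydrophobic": np.clip((1.5 - d) / 1.0, 0.0, 1.0),
        "hbond": np.clip(-d / 0.7, 0.0, 1.0),
    }


def vina_type_score(
    pose_mol: Chem.Mol, pocket: PocketModel, cutoff: float = _INTERACTION_CUTOFF
) -> DockScore:
    """Score-only evaluation of the empirical docking function (no pose search).

    More negative = better fit. If no protein atom lies within the interaction
    cutoff, the interaction terms are all zero and ``no_contact`` is flagged.
    """
    heavy_idx = [a.GetIdx() for a in pose_mol.GetAtoms() if a.GetAtomicNum() > 1]
    lig_pos = np.asarray(pose_mol.GetConformer().GetPositions())[heavy_idx]
    l_hydro, l_don, l_acc, l_rad = _ligand_vina_types(pose_mol)
    n_rot = int(Descriptors.NumRotatableBonds(pose_mol))

    if len(pocket) == 0:
        return DockScore(0.0, {k: 0.0 for k in _TERM_WEIGHTS}, n_rot, no_contact=True)
    p_hydro, p_don, p_acc, p_rad = _protein_vina_types(pocket)
    d = np.linalg.norm(lig_pos[:, None, :] - pocket.coords[None, :, :], axis=-1)
    within = d <= cutoff
    if not within.any():
        return DockScore(0.0, {k: 0.0 for k in _TERM_WEIGHTS}, n_rot, no_contact=True)
    surf = d - l_rad[:, None] - p_rad[None, :]
    terms = vina_terms(surf)
    hydro_pair = l_hydro[:, None] & p_hydro[None, :]
    hb_pair = (l_don[:, None] & p_acc[None, :]) | (l_acc[:, None] & p_don[None, :])
    sums = {
        "gauss1": float((terms["gauss1"] * within).sum()),
        "gauss2": float((terms["gauss2"] * within).sum()),
        "repulsion": float((terms["repulsion"] * within).sum()),
        "hydrophobic": float((terms["hydrophobic"] * within * hydro_pair).sum()),
        "hbond": float((terms["hbond"] * within * hb_pair).sum()),
    }
    raw = sum(_TERM_WEIGHTS[k] * v for k, v in sums.items())
    value = raw / (1.0 + _ROTOR_WEIGHT * n_rot)
    return DockScore(float(value), sums, n_rot)


# ---------------------------------------------------------------------------
# IntSim: typed contact-pair features and the pluggable affinity estimator
# ---------------------------------------------------------------------------

PROTEIN_ELEMENTS = ("C", "N", "O", "S")

# canonical ligand atom types "symbol;valence;heavy_neighbors;n_H;aromatic;ring"
DEFAULT_LIGAND_TYPES = (
    "C;4;0;4;0;0", "C;4;1;3;0;0", "C;4;2;2;0;0", "C;4;3;1;0;0", "C;4;4;0;0;0",
    "C;4;2;2;0;1", "C;4;3;1;0;1", "C;4;4;0;0;1",
    "C;4;2;1;1;1", "C;4;3;0;1;1",
    "C;4;1;2;0;0", "C;4;2;1;0;0", "C;4;3;0;0;0", "C;4;2;0;0;1", "C;4;1;1;0;0",
    "N;3;1;2;0;0", "N;3;2;1;0;0", "N;3;3;0;0;0", "N;3;3;0;0;1",
    "N;3;2;0;1;1", "N;3;2;1;1;1", "N;3;3;0;1;1", "N;3;1;0;0;0",
    "N;4;1;3;0;0", "N;4;2;2;0;0", "N;4;3;1;0;0", "N;4;4;0;0;0", "N;4;4;0;0;1",
    "O;2;1;1;0;0", "O;2;2;0;0;0", "O;2;1;0;0;0", "O;2;2;0;0;1", "O;1;1;0;0;0",
    "O;2;2;0;1;1",
    "S;2;1;1;0;0", "S;2;2;0;0;0", "S;2;2;0;0;1", "S;2;2;0;1;1",
    "S;4;3;0;0;0", "S;6;4;0;0;0",
    "F;1;1;0;0;0", "Cl;1;1;0;0;0", "Br;1;1;0;0;0", "I;1;1;0;0;0",
    "P;5;4;0;0;0",
    "other",
)


def ligand_atom_type(atom: Chem.Atom) -> str:
    """ECIF-style ligand atom type string (H-explicit and H-implicit agree)."""
    heavy_deg = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
    n_h = atom.GetTotalNumHs(includeNeighbors=True)
    return ";".join(
        [
            atom.GetSymbol(),
            str(atom.GetExplicitValence() + atom.GetNumImplicitHs()),
            str(heavy_deg),
            str(n_h),
            str(int(atom.GetIsAromatic())),
            str(int(atom.IsInRing())),
        ]
    )


@dataclass(frozen=True)
class ECIFVocabulary:
    """Fixed (protein element × ligand type) bin vocabulary."""

    protein_elements: tuple[str, ...] = PROTEIN_ELEMENTS
    ligand_types: tuple[str, ...] = DEFAULT_LIGAND_TYPES

    def __len__(self) -> int:
        return len(self.protein_elements) * len(self.ligand_types)

    def index(self, protein_element: str, ligand_type: str) -> int | None:
        try:
            pi = self.protein_elements.index(protein_element)
        except ValueError:
            return None
        try:
            li = self.ligand_types.index(ligand_type)
        except ValueError:
            li = len(self.ligand_types) - 1  # "other" bucket
        return pi * len(self.ligand_types) + li

    def labels(self) -> list[str]:
        return [f"{p}-{l}" for p in self.protein_elements for l in self.ligand_types]


_Z_TO_SYMBOL = {6: "C", 7: "N", 8: "O", 16: "S"}


def ecif_features(
    pose_mol: Chem.Mol,
    pocket: PocketModel,
    cutoff: float = 6.0,
    vocabulary: ECIFVocabulary | None = None,
) -> np.ndarray:
    """Counts of typed (protein atom, ligand atom) pairs within ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    vocab = vocabulary or ECIFVocabulary()
    counts = np.zeros(len(vocab), dtype=int)
    if len(pocket) == 0:
        return counts
    heavy = [a for a in pose_mol.GetAtoms() if a.GetAtomicNum() > 1]
    lig_pos = np.asarray(pose_mol.GetConformer().GetPositions())[[a.GetIdx() for a in heavy]]
    ltypes = [ligand_atom_type(a) for a in heavy]
    d = np.linalg.norm(lig_pos[:, None, :] - pocket.coords[None, :, :], axis=-1)
    li, pi = np.nonzero(d <= cutoff)
    for l, p in zip(li, pi):
        sym = _Z_TO_SYMBOL.get(int(pocket.elements[p]))
        if sym is None:
            continue
        idx = vocab.index(sym, ltypes[l])
        if idx is not None:
            counts[idx] += 1
    return counts


class EstimatorMissingError(ValueError):
    def __init__(self) -> None:
        super().__init__(
            "no affinity estimator supplied: pass a fitted callable or sklearn "
            "regressor mapping contact-feature vectors to pAct "
            "(see scoring.fit_synthetic_estimator for a test-scale example)"
        )


def int_sim(
    pose_mol: Chem.Mol,
    pocket: PocketModel,
    estimator,
    cutoff: float = 6.0,
    vocabulary: ECIFVocabulary | None = None,
) -> float:
    """Estimated affinity (pAct) of a pose from its typed contact counts."""
    if estimator is None:
        raise EstimatorMissingError()
    feats = ecif_features(pose_mol, pocket, cutoff, vocabulary)
    if hasattr(estimator, "predict"):
        return float(np.asarray(estimator.predict(feats.reshape(1, -1))).ravel()[0])
    return float(estimator(feats))


def fit_synthetic_estimator(seed: int = 0, vocabulary: ECIFVocabulary | None = None):
    """Fit a small ridge regressor on synthetic contact-count data.

    A stand-in for a production affinity model: targets are a sparse linear
    function of the counts plus noise, fit at run time so nothing binary is
    stored. Suitable only for exercising the IntSim plumbing.
    """
    from sklearn.linear_model import Ridge

    vocab = vocabulary or ECIFVocabulary()
    rng = np.random.default_rng(seed)
    n = 400
    X = rng.poisson(1.0, size=(n, len(vocab)))
    true_w = np.zeros(len(vocab))
    hot = rng.choice(len(vocab), size=12, replace=False)
    true_w[hot] = rng.normal(0.2, 0.1, size=12)
    y = 5.0 + X @ true_w + rng.normal(0, 0.2, size=n)
    model = Ridge(alpha=1.0)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# Normalization and fusion
# ---------------------------------------------------------------------------


@dataclass
class PoseScore:
    """The four metrics of one pose, raw and normalized, plus the fused CS."""

    sim2d: float
    sim3d: float
    dock_raw: float = 0.0
    dock_norm: float = 0.0
    int_sim_raw: float = 0.0
    int_sim_norm: float = 0.0
    cs: float = 0.0
    ecif: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def metric_vector(self) -> np.ndarray:
        return np.array([self.sim2d, self.sim3d, self.dock_norm, self.int_sim_norm])


def _minmax(value: float, worst: float, best: float) -> float:
    if worst == best:
        raise ValueError("normalization range has zero width")
    return float(np.clip((value - worst) / (best - worst), 0.0, 1.0))


def normalize_metrics(
    sim2d: float,
    sim3d: float,
    dock_raw: float,
    int_sim_raw: float,
    config: PipelineConfig | None = None,
) -> PoseScore:
    """Linear min–max mapping of the raw metrics onto [0, 1] with clamping.

    The docking score range runs (worst → best) = (0 → −12) energy units, so
    more negative scores map to higher values; estimated affinity runs pAct
    (2 → 12). The two similarities already live in [0, 1] and pass through.
    """
    cfg = config or PipelineConfig()
    return PoseScore(
        sim2d=float(np.clip(sim2d, 0.0, 1.0)),
        sim3d=float(np.clip(sim3d, 0.0, 1.0)),
        dock_raw=dock_raw,
        dock_norm=_minmax(dock_raw, *cfg.dock_norm_range),
        int_sim_raw=int_sim_raw,
        int_sim_norm=_minmax(int_sim_raw, *cfg.affinity_norm_range),
    )


def confidence_score(score: PoseScore, weights: ScoringWeights | None = None) -> float:
    """CS = α·2Dsim + β·3Dsim + γ·IntDock + δ·IntSim; stored on the PoseScore."""
    w = weights or ScoringWeights()
    score.cs = float(w.as_array() @ score.metric_vector())
    return score.cs


# ---------------------------------------------------------------------------
# Weight optimization: exhaustive grid search maximizing F1
# ---------------------------------------------------------------------------


@dataclass
class WeightSearchResult:
    weights: ScoringWeights
    f1: float
    threshold: float


def _best_f1_per_column(cs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-threshold F1 for every weight column of a (n, m) score matrix."""
    n = cs.shape[0]
    order = np.argsort(-cs, axis=0, kind="stable")
    y_sorted = y[order]  # (n, m)
    tp = np.cumsum(y_sorted, axis=0)
    k = np.arange(1, n + 1)[:, None]
    pos = y.sum()
    f1 = 2.0 * tp / (k + pos)
    best_k = np.argmax(f1, axis=0)
    best_f1 = f1[best_k, np.arange(cs.shape[1])]
    cs_sorted = np.take_along_axis(cs, order, axis=0)
    thresholds = cs_sorted[best_k, np.arange(cs.shape[1])]
    return best_f1, thresholds


def optimize_weights(
    labeled: Sequence[tuple[PoseScore, bool]] | tuple[np.ndarray, np.ndarray],
    grid_step: float = 0.027,
    weight_sum_range: tuple[float, float] = (0.95, 1.05),
    fixed_threshold: float | None = None,
) -> WeightSearchResult:
    """Exhaustive grid search over fusion weights maximizing F1.

    ``labeled`` is either a sequence of (PoseScore, success) pairs or a
    pre-built ``(X, y)`` with X of shape (n, 4) holding the normalized metrics
    and y boolean success flags (RMSD < 2 Å). Weights are scanned on the
    ``grid_step`` lattice of [0, 1]^4 restricted to sums inside
    ``weight_sum_range``. For each combination the classification threshold on
    CS is the one maximizing F1 (or ``fixed_threshold`` when given). Ties are
    broken by the first combination in lexicographic grid order.
    """
    if isinstance(labeled, tuple) and len(labeled) == 2:
        X, y = np.asarray(labeled[0], float), np.asarray(labeled[1], bool)
    else:
        X = np.array([s.metric_vector() for s, _ in labeled], dtype=float)
        y = np.array([bool(flag) for _, flag in labeled])
    if y.all() or not y.any():
        raise ValueError("need both successful and failed poses to optimize weights")

    vals = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    grids = np.meshgrid(vals, vals, vals, vals, indexing="ij")
    W = np.stack([g.ravel() for g in grids], axis=1)  # lexicographic order
    sums = W.sum(axis=1)
    W = W[(sums >= weight_sum_range[0] - 1e-9) & (sums <= weight_sum_range[1] + 1e-9)]
    if len(W) == 0:
        raise ValueError("weight grid empty under the sum restriction")

    best_f1_global = -1.0
    best_w = None
    best_thr = 0.0
    chunk = 20000
    for start in range(0, len(W), chunk):
        Wc = W[start : start + chunk]
        cs = X @ Wc.T  # (n, m)
        if fixed_threshold is None:
            f1s, thrs = _best_f1_per_column(cs, y)
        else:
            pred = cs >= fixed_threshold
            tp = (pred & y[:, None]).sum(axis=0)
            fp = (pred & ~y[:, None]).sum(axis=0)
            fn = (~pred & y[:, None]).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f1s = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
            thrs = np.full(len(Wc), fixed_threshold)
        j = int(np.argmax(f1s))
        if f1s[j] > best_f1_global + 1e-12:
            best_f1_global = float(f1s[j])
            best_w = Wc[j]
            best_thr = float(thrs[j])
    a, b, g, d = (float(v) for v in best_w)
    return WeightSearchResult(
        weights=ScoringWeights(alpha=a, beta=b, gamma=g, delta=d),
        f1=best_f1_global,
        threshold=best_thr,
    )
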