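"""Pose-accuracy evaluation: symmetry-aware RMSD, leave-one-out benchmarking,
binding-site multiplicity, and hotspot recovery.

A predicted pose is successful when its heavy-atom RMSD to the crystal pose,
measured in the frame obtained by superposing the protein backbones, is below
2.0 Å. The RMSD is minimized over graph automorphisms of the ligand so that
topological symmetry (e.g. a flipped phenyl ring) is not penalized.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.cluster.hierarchy import fcluster, linkage

from fragmint import pipeline, templates
from fragmint.chemprep import StandardLigand
from fragmint.config import PipelineConfig
from fragmint.refine import PocketModel
from fragmint.templates import TemplatePool


def backbone_superpose(
    prot_a, prot_b
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) superposition of protein A's backbone onto B's.

    Cα atoms are paired by (chain, residue number). Returns (rotation,
    translation, fit RMSD) such that ``x @ R.T + t`` maps A-frame coordinates
    into B's frame. Requires at least 3 matched Cα pairs.
    """
    ca_a = prot_a[(prot_a.atom_name == "CA")]
    ca_b = prot_b[(prot_b.atom_name == "CA")]
    key_a = {(c, r): i for i, (c, r) in enumerate(zip(ca_a.chain_id, ca_a.res_id))}
    pairs = [
        (key_a[(c, r)], j)
        for j, (c, r) in enumerate(zip(ca_b.chain_id, ca_b.res_id))
        if (c, r) in key_a
    ]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched backbone atoms; need >= 3")
    A = np.asarray(ca_a.coord, float)[[i for i, _ in pairs]]
    B = np.asarray(ca_b.coord, float)[[j for _, j in pairs]]
    return kabsch(A, B)


def kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation + translation minimizing RMSD of A onto B."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A @ R.T + t - B) ** 2, axis=1))))
    return R, t, rmsd


class GraphMismatchError(ValueError):
    pass


def symmetry_rmsd(
    mol_a: Chem.Mol,
    mol_b: Chem.Mol,
    max_matches: int = 10000,
) -> float:
    """Minimum heavy-atom RMSD over graph automorphisms, no re-fitting.

    Both molecules must share the same molecular graph; coordinates are
    compared in the common frame. If the automorphism count exceeds
    ``max_matches`` the search falls back to the enumerated subset (and the
    index-matched mapping, always included).
    """
    a = Chem.RemoveHs(Chem.Mol(mol_a))
    b = Chem.RemoveHs(Chem.Mol(mol_b))
    if a.GetNumAtoms() != b.GetNumAtoms():
        raise GraphMismatchError("different heavy-atom counts")
    matches = b.GetSubstructMatches(a, uniquify=False, maxMatches=max_matches)
    if not matches:
        raise GraphMismatchError("molecular graphs do not match")
    pa = np.asarray(a.GetConformer().GetPositions())
    pb = np.asarray(b.GetConformer().GetPositions())
    best = np.inf
    for m in matches:
        rmsd = np.sqrt(np.mean(np.sum((pa - pb[list(m)]) ** 2, axis=1)))
        best = min(best, float(rmsd))
    return best


@dataclass
class BenchmarkEntry:
    """One leave-one-out benchmark case: a query with known crystal pose."""

    entry_id: str
    query: StandardLigand  # mol3d conformer 0 = ground-truth crystal pose
    pool: TemplatePool
    pocket: PocketModel | None = None
    truth_mol: Chem.Mol | None = None  # defaults to query.mol3d
    # source complex of the query's crystal pose: when set, leave-one-out
    # removes exactly that pool entry (an identical ligand re-determined in a
    # different structure remains an eligible template); when None, every
    # entry sharing the query's identity key is removed instead
    self_structure_id: str | None = None


@dataclass
class BenchmarkResult:
    table: pd.DataFrame  # per entry: rmsd, success, cs, template, flags
    success_rate: float  # % over evaluated entries
    success_rate_high_confidence: float  # % restricted to CS above the gate
    n_no_template: int
    curve: pd.DataFrame  # cumulative (rmsd_threshold, pct_leq)


def cumulative_curve(rmsds: list[float], n_points: int = 50) -> pd.DataFrame:
    vals = np.sort([r for r in rmsds if np.isfinite(r)])
    if len(vals) == 0:
        return pd.DataFrame(columns=["rmsd_threshold", "pct_leq"])
    thresholds = np.linspace(0.0, float(vals.max()), n_points)
    pct = [100.0 * float(np.mean(vals <= t)) for t in thresholds]
    return pd.DataFrame({"rmsd_threshold": thresholds, "pct_leq": pct})


def run_leave_one_out(
    entries: list[BenchmarkEntry],
    config: PipelineConfig | None = None,
    estimator=None,
    seed: int = 0,
    empty_pool_convention: str = "exclude",
) -> BenchmarkResult:
    """Leave-one-out benchmark over a set of ligand–protein complexes.

    For each entry the query's own source complex (``self_structure_id``, or
    every entry with the query's identity key when no source id is given) is
    removed from the template pool, the full pipeline is run, the argmax-CS
    pose is kept, and its symmetry-aware
    heavy-atom RMSD to the crystal pose is computed (poses are generated in
    the crystal frame here, so no backbone superposition is needed; apply
    :func:`backbone_superpose` upstream when receptors differ).

    ``empty_pool_convention``: "exclude" drops entries with no remaining
    template from the rates (counted in ``n_no_template``); "count-as-failure"
    scores them as failed predictions.
    """
    if empty_pool_convention not in ("exclude", "count-as-failure"):
        raise ValueError("empty_pool_convention must be 'exclude' or 'count-as-failure'")
    cfg = config or PipelineConfig()
    rows = []
    for entry in entries:
        if entry.self_structure_id is not None:
            pool = TemplatePool(
                protein_id=entry.pool.protein_id,
                entries=[
                    e for e in entry.pool.entries
                    if e.structure_id != entry.self_structure_id
                ],
            )
        else:
            pool = templates.exclude_self(entry.pool, entry.query.key)
        poses = (
            pipeline.predict_poses(
                entry.query, pool, entry.pocket, cfg, estimator=estimator, seed=seed
            )
            if len(pool)
            else []
        )
        best = pipeline.best_pose(poses)
        truth = entry.truth_mol if entry.truth_mol is not None else entry.query.mol3d
        if best is None:
            rows.append(
                {
                    "entry_id": entry.entry_id,
                    "rmsd": np.nan,
                    "success": False,
                    "cs": np.nan,
                    "template_id": None,
                    "no_template": True,
                    "flags": "",
                }
            )
            continue
        rmsd = symmetry_rmsd(best.mol, truth)
        rows.append(
            {
                "entry_id": entry.entry_id,
                "rmsd": rmsd,
                "success": bool(rmsd < cfg.success_rmsd),
                "cs": best.cs,
                "template_id": best.template_id,
                "no_template": False,
                "flags": ";".join(best.flags),
            }
        )
    table = pd.DataFrame(rows)
    n_no_template = int(table["no_template"].sum())
    if empty_pool_convention == "exclude":
        eval_table = table[~table["no_template"]]
    else:
        eval_table = table
    if len(eval_table):
        success_rate = 100.0 * float(eval_table["success"].mean())
        hc = eval_table[eval_table["cs"] > cfg.cs_threshold]
        hc_rate = 100.0 * float(hc["success"].mean()) if len(hc) else float("nan")
    else:
        success_rate, hc_rate = float("nan"), float("nan")
    return BenchmarkResult(
        table=table,
        success_rate=success_rate,
        success_rate_high_confidence=hc_rate,
        n_no_template=n_no_template,
        curve=cumulative_curve(list(table["rmsd"].dropna())),
    )


def cluster_binding_sites(
    ligand_centroids: np.ndarray, linkage_cutoff: float = 8.0
) -> tuple[int, np.ndarray]:
    """Single-linkage clustering of ligand centroids into discrete sites.

    Returns (site count, per-pose labels). Labels are renumbered 0..k-1 in
    order of first occurrence so they are deterministic.
    """
    pts = np.asarray(ligand_centroids, float)
    if len(pts) == 0:
        return 0, np.array([], dtype=int)
    if len(pts) == 1:
        return 1, np.array([0])
    Z = linkage(pts, method="single")
    raw = fcluster(Z, t=linkage_cutoff, criterion="distance")
    relabel: dict[int, int] = {}
    labels = np.array([relabel.setdefault(r, len(relabel)) for r in raw])
    return len(relabel), labels


def hotspot_recovery(
    predicted, reference, cutoff: float = 2.0
) -> tuple[float, pd.DataFrame]:
    """Spatial + chemical recovery of experimental fragment hotspots.

    For every predicted fragment: the minimum centroid–centroid distance to
    any reference fragment and the maximum 2D Tanimoto to any reference
    fragment. Returns the fraction of predicted fragments within ``cutoff`` Å
    and the per-fragment table.
    """
    if len(reference) == 0:
        raise ValueError("empty reference fragment set")
    ref_centroids = np.array([f.centroid() for f in reference])
    rows = []
    for frag in predicted:
        d = np.linalg.norm(ref_centroids - frag.centroid(), axis=1)
        sims = [templates.tanimoto2d(frag.mol, rf.mol) for rf in reference]
        rows.append(
            {
                "fragment_key": frag.key,
                "min_centroid_distance": float(d.min()),
                "max_similarity": float(max(sims)),
            }
        )
    table = pd.DataFrame(rows)
    fraction = float((table["min_centroid_distance"] <= cutoff).mean()) if len(table) else 0.0
    return fraction, table


def posebusters_check(sdf_path: str, receptor_path: str | None = None) -> dict:
    """Optional adapter around an external pose-plausibility checker.

    Shells out to a ``bust`` executable if one is installed; otherwise reports
    unavailability. Never reimplements the checks.
    """
    exe = shutil.which("bust")
    if exe is None:
        return {"available": False, "reason": "no 'bust' executable on PATH"}
    cmd = [exe, sdf_path]
    if receptor_path:
        cmd += ["-p", receptor_path]
    proc = subprocess.run(cmd, capture_output=True, text=True, timeout=600)
    return {
        "available": True,
        "returncode": proc.returncode,
        "stdout": proc.stdout,
        "stderr": proc.stderr,
    }
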