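"""End-to-end pose prediction for one query: templates → align → refine → score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from fragmint import chemprep, field_align, refine, scoring, templates
from fragmint.config import PipelineConfig
from fragmint.refine import PocketModel


@dataclass
class ScoredPose:
    """A refined candidate pose carrying the four metrics and the fused CS."""

    mol: Chem.Mol  # H-explicit refined pose
    pose_id: str
    template_id: str
    score: scoring.PoseScore
    flags: list[str] = field(default_factory=list)

    @property
    def cs(self) -> float:
        return self.score.cs

    def heavy_coords(self) -> np.ndarray:
        pos = np.asarray(self.mol.GetConformer().GetPositions())
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        return pos[idx]


def predict_poses(
    query: chemprep.StandardLigand,
    pool: templates.TemplatePool,
    pocket: PocketModel | None,
    config: PipelineConfig | None = None,
    estimator=None,
    seed: int = 0,
    field_model: field_align.FieldModel | None = None,
) -> list[ScoredPose]:
    """All candidate poses of a query against a template pool, CS-sorted.

    Selects up to ``n_templates`` templates above the similarity threshold,
    aligns every query conformer to each template pose (up to
    ``n_poses_per_template`` alignments kept per template → ≤ 9 candidates),
    refines each candidate with MCS tethering inside the rigid pocket, and
    scores it. Returns candidates sorted by confidence score descending; an
    empty list means no usable template.
    """
    cfg = config or PipelineConfig()
    model = field_model or field_align.FieldModel()
    matches = templates.select_templates(
        query, pool, k=cfg.n_templates, threshold=cfg.template_similarity_threshold,
        n_bits=cfg.fingerprint_bits,
    )
    if not matches:
        return []
    if query.mol3d is None or query.mol3d.GetNumConformers() == 0:
        chemprep.generate_conformers(
            query, n_requested=cfg.n_conformers, seed=seed, prune_rmsd=cfg.conformer_prune_rmsd
        )

    out: list[ScoredPose] = []
    for match in matches:
        template_mol = match.entry.ligand.mol3d
        aligned = field_align.align_to_template(
            query,
            template_mol,
            model=model,
            n_poses=cfg.n_poses_per_template,
            seed=seed,
            template_id=match.entry.structure_id,
        )
        mapping = refine.find_mcs(
            query.mol, match.entry.ligand.mol, min_atoms=cfg.mcs_min_atoms
        )
        for rank, pose in enumerate(aligned):
            flags = list(pose.flags)
            tether = None
            if mapping is None:
                flags.append("no_tether")
            else:
                tether = refine.make_tether(
                    pose.mol, mapping, cfg.tether_force_constant, cfg.tether_tolerance
                )
            result = refine.tethered_minimize(
                pose.mol, pocket, tether, clash_floor=cfg.clash_floor
            )
            flags.extend(result.flags)
            sim3d = field_align.field_similarity(result.mol, template_mol, model)
            if pocket is not None and len(pocket) > 0:
                dock = scoring.vina_type_score(result.mol, pocket)
                if dock.no_contact:
                    flags.append("no_pocket_contact")
                dock_raw = dock.value
                affinity = (
                    scoring.int_sim(result.mol, pocket, estimator, cutoff=cfg.ecif_cutoff)
                    if estimator is not None
                    else cfg.affinity_norm_range[0]
                )
                if estimator is None:
                    flags.append("no_estimator")
            else:
                dock_raw, affinity = 0.0, cfg.affinity_norm_range[0]
                flags.append("no_pocket")
            score = scoring.normalize_metrics(
                sim2d=match.similarity2d,
                sim3d=sim3d,
                dock_raw=dock_raw,
                int_sim_raw=affinity,
                config=cfg,
            )
            scoring.confidence_score(score, cfg.weights)
            score.flags = flags
            out.append(
                ScoredPose(
                    mol=result.mol,
                    pose_id=f"{query.key}|{match.entry.structure_id}|{rank}",
                    template_id=match.entry.structure_id,
                    score=score,
                    flags=flags,
                )
            )
    out.sort(key=lambda p: (-p.cs, p.pose_id))
    return out


def best_pose(poses: list[ScoredPose]) -> ScoredPose | None:
    """Final pose of a query: argmax CS over all candidates."""
    return poses[0] if poses else None


def poses_to_table(poses: list[ScoredPose]):
    """Score table: one row per candidate with the four metrics and CS."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pose_id": p.pose_id,
                "template_id": p.template_id,
                "sim2d": p.score.sim2d,
                "sim3d": p.score.sim3d,
                "dock_raw": p.score.dock_raw,
                "dock_norm": p.score.dock_norm,
                "int_sim_norm": p.score.int_sim_norm,
                "cs": p.cs,
                "flags": ";".join(p.flags),
            }
            for p in poses
        ]
    )
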