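"""Pipeline-wide configuration: every threshold and weight in one place."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScoringWeights:
    """Fusion weights for the confidence score CS = α·2Dsim + β·3Dsim + γ·IntDock + δ·IntSim.

    Defaults are the grid-search optimum reported for the benchmark set.
    """

    alpha: float = 0.027
    beta: float = 0.324
    gamma: float = 0.378
    delta: float = 0.270

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"weight {name}={v} outside [0, 1]")

    def as_array(self):
        import numpy as np

        return np.array([self.alpha, self.beta, self.gamma, self.delta])


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pose-prediction / fragmentation pipeline.

    Attributes
    ----------
    template_similarity_threshold:
        Strict lower bound on 2D Tanimoto for a template to be eligible (0.3).
    n_templates:
        Number of top templates carried forward (3).
    n_conformers:
        Diverse conformers generated per query ligand (5).
    conformer_prune_rmsd:
        Heavy-atom RMSD (Å) below which two conformers are redundant (0.5).
    n_poses_per_template:
        Alignment poses kept per template (3); with 3 templates → ≤ 9 candidates.
    cs_threshold:
        Confidence-score gate for fragmentation (0.6).
    cs_gate_inclusive:
        Whether the gate is CS ≥ threshold (True) or CS > threshold (False).
    success_rmsd:
        Pose-prediction success cutoff in Å (strict: RMSD < 2.0).
    pact_threshold:
        Activity-curation cutoff in pAct units (5.0 ⇔ 10 µM).
    dock_norm_range:
        (worst, best) raw docking energies mapped linearly to [0, 1].
    affinity_norm_range:
        (worst, best) predicted pAct mapped linearly to [0, 1].
    pocket_radius:
        Residues with any heavy atom within this distance (Å) of the template
        ligand define the pocket (8.0).
    contact_cutoff:
        Heavy-atom distance (Å) defining a fragment–residue contact (5.0).
    ecif_cutoff:
        Distance cutoff (Å) for interaction-feature pair counting (6.0).
    mcs_min_atoms:
        Minimum MCS heavy-atom count for tethering; below it the pose passes
        through untethered with a warning flag (3).
    tether_force_constant:
        Harmonic tether spring constant, kcal/mol/Å² (10.0).
    tether_tolerance:
        Allowed displacement (Å) of tethered atoms after refinement (0.5).
    clash_floor:
        Minimum acceptable ligand–protein heavy-atom distance (Å) (2.0).
    fragment_enumeration_cap:
        Molecules with more cleavable bonds than this fall back to bounded
        subgraph enumeration (14).
    fragment_subgraph_limit:
        Maximum minimal-fragment count per enumerated subgraph in the capped
        regime (8).
    grid_step:
        Weight-grid resolution of the F1 search (0.027).
    weight_sum_range:
        Allowed total weight mass on the search simplex shell.
    site_linkage_cutoff:
        Single-linkage distance (Å) separating binding sites (8.0).
    hotspot_cutoff:
        Centroid distance (Å) counting a predicted fragment as recovering an
        experimental hotspot (2.0).
    fingerprint_bits:
        Folded length of the radius-2 circular fingerprint (2048).
    """

    template_similarity_threshold: float = 0.3
    n_templates: int = 3
    n_conformers: int = 5
    conformer_prune_rmsd: float = 0.5
    n_poses_per_template: int = 3
    cs_threshold: float = 0.6
    cs_gate_inclusive: bool = True
    success_rmsd: float = 2.0
    pact_threshold: float = 5.0
    dock_norm_range: tuple[float, float] = (0.0, -12.0)
    affinity_norm_range: tuple[float, float] = (2.0, 12.0)
    pocket_radius: float = 8.0
    contact_cutoff: float = 5.0
    ecif_cutoff: float = 6.0
    mcs_min_atoms: int = 3
    tether_force_constant: float = 10.0
    tether_tolerance: float = 0.5
    clash_floor: float = 2.0
    fragment_enumeration_cap: int = 14
    fragment_subgraph_limit: int = 8
    grid_step: float = 0.027
    weight_sum_range: tuple[float, float] = (0.95, 1.05)
    site_linkage_cutoff: float = 8.0
    hotspot_cutoff: float = 2.0
    fingerprint_bits: int = 2048
    weights: ScoringWeights = field(default_factory=ScoringWeights)

    def passes_cs_gate(self, cs: float) -> bool:
        if self.cs_gate_inclusive:
            return cs >= self.cs_threshold
        return cs > self.cs_threshold
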