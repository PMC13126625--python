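# fragmint

Template-based ligand binding-pose prediction and 3D-annotated fragment
libraries for fragment-based drug discovery (FBDD).

Most known bioactive molecules have no experimentally determined binding pose:
public bioactivity databases dwarf the set of solved protein–ligand crystal
structures. `fragmint` converts that non-structural activity data into 3D
structural hypotheses by exploiting a simple observation — a ligand that is
similar to a crystallographically resolved binder usually binds the same way.
The resulting high-confidence poses are then exhaustively deconstructed into
chemical fragments that inherit their parent's coordinates, producing a
structurally annotated fragment library that supports interaction-fingerprint
bioisostere queries and attachment-vector scaffold hopping.

## Method

For a query ligand with known activity against a protein but no structure:

1. **Template selection** — all crystallographic ligands of the protein form
   the template pool; the three most similar by 2D Tanimoto (radius-2 Morgan
   fingerprints) are kept if their similarity exceeds 0.3.
2. **Field alignment** — up to 5 diverse ETKDGv2/MMFF94s conformers of the
   query are rigidly superposed onto each template pose by maximizing a
   Gaussian molecular-field similarity (steric + electrostatic channels,
   Carbo cosine normalization), multi-start quasi-Newton search.
3. **Tethered refinement** — each aligned pose is locally minimized inside the
   rigid pocket (MMFF94s + Lennard-Jones/Coulomb protein terms) with the
   query–template maximum common substructure harmonically restrained to its
   aligned position.
4. **Confidence scoring** — four normalized metrics are fused linearly:

   CS = α·2Dsim + β·3Dsim + γ·IntDock + δ·IntSim

   with (α, β, γ, δ) = (0.027, 0.324, 0.378, 0.270): template 2D similarity,
   field 3D similarity, a score-only empirical docking evaluation, and an
   interaction-feature affinity estimate. The weights maximize F1 for
   classifying successful poses (RMSD < 2 Å) in an exhaustive grid search,
   reproduced by `scoring.optimize_weights`. The best-CS pose is retained;
   poses with CS ≥ 0.6 feed fragmentation.
5. **Exhaustive fragmentation** — every connected union of minimal BRICS
   fragments is enumerated with coordinates inherited from the parent pose,
   then filtered for fragment-likeness (MW ≤ 300, HBD ≤ 3, HBA ≤ 6,
   1 ≤ rings ≤ 4, rotatable bonds ≤ 5) and organized into unique
   (fragment, protein) pairs with their contact-residue environments.

## Worked example

Predict the pose of a congeneric analog in the bundled synthetic benchmark (a
rigid glycine-shell pocket holding a trisubstituted-benzene series whose true
poses are known by construction):

```python
from fragmint import fixtures, pipeline, validation
from fragmint.config import PipelineConfig
from fragmint.templates import TemplatePool

cfg = PipelineConfig()
toy = fixtures.make_toy_complex(seed=0, n_queries=4)
entry = fixtures.toy_benchmark_entries(toy, seed=0)[1]   # the bromo analog
pool = TemplatePool(entry.pool.protein_id, [
    e for e in entry.pool.entries if e.structure_id != entry.self_structure_id
])
poses = pipeline.predict_poses(entry.query, pool, entry.pocket, cfg, seed=0)
print(pipeline.poses_to_table(poses).head(3).to_string(index=False))
print("RMSD:", round(validation.symmetry_rmsd(poses[0].mol, entry.truth_mol), 3))
```

prints

```
                             pose_id template_id  sim2d    sim3d  dock_raw  dock_norm  int_sim_norm       cs        flags
OTUYBYTUBWJBLO-UHFFFAOYSA-N|TOYC01|0      TOYC01    1.0 0.999702 -0.976781   0.081398           0.0 0.381672 no_estimator
OTUYBYTUBWJBLO-UHFFFAOYSA-N|TOYC01|1      TOYC01    1.0 0.979686 -0.893564   0.074464           0.0 0.372565 no_estimator
OTUYBYTUBWJBLO-UHFFFAOYSA-N|TOYC00|0      TOYC00    0.5 0.970557 -1.028715   0.085726           0.0 0.360365 no_estimator
RMSD: 0.051
```

The top pose uses the exact-copy template (`TOYC01`, 2D similarity 1.0, field
similarity 0.9997) and lands 0.05 Å from the crystal pose — the self-recovery
scenario. Rows below it are poses from merely congeneric templates; the CS
column ranks them. `dock_raw` is the score-only docking energy (more negative
is better) and IntSim is zero here because no affinity estimator was supplied
(flagged per pose).

A command-line interface wraps the same functionality:

```bash
fragmint fixtures --seed 0 --out fixtures_out     # regenerate the toy system
fragmint benchmark --seed 0                        # leave-one-out benchmark
fragmint predict --smiles "Cc1cc(O)cc(Br)c1" --pool <pool_dir> --receptor <pdb>
fragmint fragment --poses poses.sdf --out fragments.sdf
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end from the given seed: it regenerates the
synthetic benchmark, runs the leave-one-out pose prediction and reports the
success rate, reruns the F1 weight-grid search on a planted scored dataset,
and fragments the recovered poses into the filtered fragment library, writing
the target JSON to `--out`.

## Layout

| Module | Role |
| --- | --- |
| `chemprep` | pH 7 standardization, ETKDGv2 + MMFF94s conformer ensembles |
| `templates` | template pools, 2D Tanimoto selection, self-exclusion |
| `field_align` | Gaussian field similarity and rigid multi-start alignment |
| `refine` | pocket extraction, MCS tethers, tethered minimization |
| `scoring` | the four metrics, CS fusion, F1 weight-grid search |
| `fragmenter` | exhaustive BRICS decomposition, fragment-likeness filters |
| `library` | activity curation, fragment–environment pairs, scaffold analytics |
| `queries` | interaction fingerprints, bioisostere search, scaffold hopping |
| `validation` | symmetry-aware RMSD, leave-one-out benchmark, hotspot recovery |
| `fixtures` | deterministic synthetic test systems |

See `docs/methods.md` for the scientific details, parameter defaults, and
known limitations.
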