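# Methods

This note documents the models and numerical choices behind `fragmint`, what
the synthetic fixtures do and do not establish, and the design decisions made
where the procedure was genuinely open.

## Pose prediction model

The central assumption is knowledge-based: if a query ligand is chemically
similar to a ligand with a crystallographically determined pose on the same
protein, superposing the query onto that template approximates its binding
mode. The pipeline is therefore only applicable to proteins with at least one
ligand-bound structure and degrades when similar ligands adopt different
binding modes — both are intrinsic limits, not implementation artifacts.

### Ligand standardization (`chemprep`)

Inputs are stripped to their largest organic component and assigned pH 7.0
formal charges by a versioned SMARTS rule table
(`src/fragmint/data/ph7_rules.csv`): carboxylic/sulfonic/sulfinic/phosphorus
oxyacids and tetrazoles deprotonate; aliphatic amines and amidines/guanidines
protonate (once — the rule engine edits each atom at most once, so guanidine
becomes a +1 guanidinium, not +3). Borderline bases near pKa 7 (imidazole,
pyridine at 5.2, phenol at 10) stay neutral. Tautomers are not canonicalized
and stereoisomers are not enumerated: minimal intervention, reproducible
without an external protonation engine. Identity is the InChIKey of the
standardized molecule, invariant to atom order and conformers.

Conformers: ETKDGv2 embedding (fixed seed, single-threaded for determinism),
MMFF94s local minimization, then greedy energy-ordered pruning so all retained
pairs differ by symmetry-aware heavy-atom RMSD ≥ 0.5 Å; the 5 lowest-energy
survivors are kept by default. The pre-prune count (4× requested, minimum 20)
and minimizer iteration cap (500) are config-exposed; embedding failures are
retried 3 times with offset seeds before raising.

### Template selection (`templates`)

Radius-2 Morgan fingerprints folded to 2048 bits (folded length configurable —
it perturbs Tanimoto values in the third decimal). The top 3 templates with
similarity strictly above 0.3 are used. Ties break by (similarity desc, source
structure id asc) so results are independent of pool order. Duplicate template
ligands from different source structures are kept; the tie-break orders them.

### Field alignment (`field_align`)

Each heavy atom carries a spherical Gaussian. Steric channel: Grant–Pickup
density with amplitude p = 2.7 and exponent α = π(3p/(4πR³))^(2/3) for Bondi
vdW radius R, which makes each atomic Gaussian integrate to its vdW volume.
Electrostatic channel: Gasteiger partial charges as amplitudes on the same
centers and widths. Channel similarity is the Carbo cosine
O(a,b)/√(O(a,a)·O(b,b)) with the analytic two-Gaussian overlap; channels mix
50/50 by default (config-exposed) and the mix is clamped to [0, 1]. For a
fully apolar molecule the electrostatic cosine is undefined (zero
self-overlap) and falls back to the steric value.

The superposition maximizes the mixed similarity over a 6-dof rigid transform
per query conformer: 12 deterministic starts (3 principal-axis permutations ×
4 proper sign flips) plus 4 seeded random rotations, each refined by L-BFGS-B
(numeric gradients; molecules here are small). Returned poses are distinct at
heavy-atom RMSD ≥ 0.5 Å and sorted by similarity. Self-overlap is invariant
under the rigid transform and computed once.

### Tethered refinement (`refine`)

The published procedure delegates refinement to an external tethered-docking
program; `fragmint` implements a functional equivalent so the pipeline is
testable without that dependency, and defines an adapter protocol where the
external binary can be substituted. The objective is

E = E_MMFF94s(ligand) + Σ LJ(12-6) + Σ Coulomb(ε = r) + k·Σ‖x_i − x_i^ref‖²

minimized over ligand coordinates with L-BFGS-B (analytic gradients; the
protein is rigid and never moves). LJ parameters are per-element
Amber-flavoured (rmin/2, ε); protein partial charges are nonzero only at
formal-charge centers (Asp/Glu carboxylates, Lys/Arg ammonium/guanidinium).
The tether holds the query–template maximum common substructure (connected,
element + bond-order matching, minimum 3 heavy atoms, deterministic tie-break)
near its aligned coordinates: "fixed" is read as strongly restrained
(k = 10 kcal/mol/Å², tolerance 0.5 Å), not frozen, because refinement must be
able to relieve clashes. A distance² floor (0.5 Å) soft-cores the LJ term
against line-search blowups. Pockets are whole residues with any heavy atom
within 8 Å of the reference ligand; waters, ions and non-polymeric cofactors
are excluded and logged.

### Scoring (`scoring`)

- **2Dsim** — query–template Tanimoto (already in [0, 1]).
- **3Dsim** — field similarity of the refined pose against the template pose.
- **IntDock** — score-only evaluation of the published empirical docking
  terms (gauss1, gauss2, repulsion, hydrophobic, H-bond, with the published
  term weights and rotor penalty) on XS-radius surface distances, 8 Å cutoff.
  No pose search is performed. Protein atoms are typed from residue/atom-name
  tables because PDB polymers carry no explicit valence information.
- **IntSim** — an estimated affinity (pAct) from typed contact-pair counts:
  ligand atoms typed as element;valence;heavy-neighbors;H-count;aromatic;ring,
  protein atoms by element (C/N/O/S), pairs counted within 6 Å. The estimator
  is pluggable (any callable or sklearn regressor); the bundled
  `fit_synthetic_estimator` trains a ridge model on random synthetic counts at
  run time and exists solely to exercise the plumbing — it carries no pose
  information, which is why the bundled benchmark runs without it (IntSim then
  contributes a uniform 0 to every candidate instead of noise).

Normalization is linear min–max with clamping; ranges are **not** part of the
published procedure and default to dock_raw ∈ [0, −12] (more negative is
better) and pAct ∈ [2, 12], recorded in output provenance.

CS is the weighted sum of the four normalized metrics with defaults
(0.027, 0.324, 0.378, 0.270). `optimize_weights` reproduces the calibration:
an exhaustive scan of the 0.027-step grid on [0, 1]⁴ restricted to weight sums
in [0.95, 1.05] (the printed weights sum to 0.999), scoring each combination
by the best-threshold F1 for classifying successes (RMSD < 2 Å) and breaking
ties by first-in-lexicographic-order. Whether the original search fixed the
threshold or optimized it per combination is unstated; both modes exist and
per-combination optimization is the default. The best-CS pose per query is
retained; fragmentation is gated at CS ≥ 0.6 ("0.6 or greater"; the comparator
is config-exposed because a strict reading also appears).

### Fragmentation (`fragmenter`)

"Every substructure derivable from the BRICS disconnection rules" is
formalized as every connected union of minimal BRICS fragments — the unique
closure of cutting any subset of cleavable bonds and keeping each connected
piece. The minimal fragments form a graph whose edges are cleaved bonds;
enumeration of connected induced subgraphs is exact (verified against a 2^n
brute force) with a combinatorial guard: molecules with > 14 cleavable bonds
fall back to subgraphs of ≤ 8 minimal fragments and carry a truncation flag.
Fragment heavy atoms inherit parent-pose coordinates bit-identically; severed
bonds become hydrogen caps, and each cut is recorded as an attachment vector
(anchor + outward unit direction) for scaffold hopping.

Properties are computed on the hydrogen-capped fragment (the filters are
meaningless on open valences; the H-vs-dummy choice shifts MW/HBA marginally
and is recorded here as the deviation risk). Ring count is the SSSR count;
rotatable bonds use the strict definition (acyclic single bonds between
non-terminal heavy atoms, amides excluded). Filters: MW ≤ 300 Da, HBD ≤ 3,
HBA ≤ 6, 1 ≤ rings ≤ 4, rotatable bonds ≤ 5, all required simultaneously.

### Library and queries

Activity curation converts IC50/EC50/Ki/Kd to pAct = −log10(molar), keeps
records with pAct ≥ 5.0 (10 µM) or an explicit "active" label, and
deduplicates by (ligand key, protein) keeping the maximum pAct. Unique
fragment–protein pairs are keyed on (fragment InChIKey, protein accession);
binding-site identity is deliberately not part of the key. The contact
environment is every residue with a heavy atom within 5 Å of the fragment
(the source procedure never defines "protein environment" numerically; 5 Å is
the documented default).

Interaction fingerprints are sets of (residue, type) with purely geometric
detection: H-bond donor–acceptor heavy distance ≤ 3.5 Å with D–H···A ≥ 130°
when the donor hydrogen has coordinates (protein donors, modeled without
hydrogens, use distance only); π-stacking at ring-centroid distance ≤ 5.5 Å
with inter-plane angle ≤ 30° (parallel) or 60–90° (T-shaped); hydrophobic
apolar–apolar ≤ 4.5 Å; ionic opposite-formal-charge ≤ 4.5 Å; halogen
X···acceptor ≤ 3.5 Å. All thresholds are config-exposed; externally computed
fingerprints can be ingested from CSV for cross-checking. Bioisostere search
ships two modes because "replicating the exact same set of interactions" is
ambiguous: `strict` (equality after restricting to the reference residues —
the default reading) and `superset` (containment).

Scaffold hopping accepts a candidate fragment when (a) its Gaussian
shape-Tanimoto with the reference core is ≥ 0.5 and (b) it offers an
attachment point within 1.0 Å and 30° of **every** reference exit vector;
ranking is (vectors matched, shape overlap, parent CS). The optional assembly
naively bonds the reference's peripheral groups onto the matched anchors and
relaxes the product alone — no synthetic-feasibility claim.

### Validation (`validation`)

Success is symmetry-aware heavy-atom RMSD < 2.0 Å after backbone
superposition (Kabsch on Cα pairs matched by chain + residue number). The
RMSD minimizes over graph automorphisms (substructure self-matches, capped at
10⁴ with fallback to the index-matched mapping) without refitting. The
leave-one-out benchmark excludes the query's own source complex when it is
known (`self_structure_id`); identity-key-based exclusion is the fallback —
the distinction matters exactly when the same ligand was re-determined in
another structure, which is the exact-copy self-recovery scenario. Entries
with empty pools are either excluded from the rates (default, the published
convention) or counted as failures (config). Binding sites are single-linkage
clusters of ligand centroids at 8 Å (the clustering scheme is unstated in the
source; this is the documented choice). Hotspot recovery reports, per
predicted fragment, the minimum centroid distance and maximum 2D similarity
to a reference fragment set, plus the fraction within 2 Å.

## The synthetic world (`fixtures`)

The toy complex is a format-valid PDB receptor — ten glycine residues on a
7.5 Å shell (eight in-plane, two apical, seeded orientation jitter) — around
a rigid trisubstituted benzene: methyl, hydroxyl, and a variable substituent
at alternating ring positions. Queries swap the variable substituent among
distinct heteroatoms (F, Br, NH₂, SH, I) with element-typical bond lengths;
ring, methyl and hydroxyl coordinates are bit-identical across the series, so
every true pose is known by construction and unambiguous (the substitution
pattern breaks all ring symmetry). The benchmark pool also carries each
query's pose under a second source id, modeling the same ligand deposited in
two structures.

What a green toy benchmark establishes: the geometric machinery — conformer
generation, field alignment, tethering, scoring plumbing, symmetry RMSD —
recovers constructed poses end to end. What it does not establish: predictive
accuracy on real pockets (the glycine shell has no shape complementarity,
hydrogen-bonding network, or induced fit), meaningful IntDock/IntSim
discrimination (contacts are weak at 4.5+ Å, and the bundled estimator is
synthetic), or the published large-scale success rates, which depend on
external datasets. Toy CS values (~0.38) sit below the 0.6 gate for the same
reason: two of the four metrics are nearly uninformative in this world.

The planted scored dataset draws four metrics uniform on [0, 1]⁴, labels
success by thresholding the planted linear CS at its median (optionally with
Gaussian label noise), and is the ground truth for weight-recovery tests.

## Degenerate inputs and tie-breaks

- Planar/linear molecules: principal axes are padded to a proper orthonormal
  frame before generating alignment starts.
- MCS below 3 heavy atoms: the pose passes through untethered with a flag.
- No template above threshold: an empty prediction, handled by the benchmark
  convention, never an exception.
- Ligands that fail MMFF typing keep unminimized conformers (energy 0) rather
  than aborting a batch.
- All sort orders that could tie (template ranking, pose ranking, weight
  grid) have documented deterministic tie-breaks.

## Known limitations

- The refinement objective is a functional substitute for the original
  external docking engine, not a parameter-for-parameter port.
- Protein atoms are typed from residue/atom-name tables (no hydrogens, no
  bond orders); His tautomers and terminal residues are handled coarsely.
- The electrostatic/steric mix inside 3Dsim and the metric normalization
  ranges are package defaults, not published values; both are recorded in
  provenance and configurable.
- Scaffold-hop assembly is geometric; it does not assess synthesizability or
  strain beyond a single force-field relaxation.
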