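"""Ligand standardization and conformer-ensemble generation.

Standardization strips salts/solvents to the largest organic component and
assigns pH 7.0 formal charges with a versioned SMARTS rule table
(``data/ph7_rules.csv``) so the result is reproducible without an external
protonation engine. Conformers are embedded with ETKDGv2, locally minimized
with MMFF94s, and pruned so every retained pair differs by heavy-atom
RMSD >= 0.5 Å.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign
from rdkit.Chem.MolStandardize import rdMolStandardize


class LigandParseError(ValueError):
    """Input structure could not be parsed or sanitized."""


class EmptyMoleculeError(ValueError):
    """No organic component survived salt stripping."""


class ConformerGenerationError(RuntimeError):
    """3D embedding failed after retries; carries the ligand identity key."""

    def __init__(self, key: str, message: str = "conformer embedding failed"):
        super().__init__(f"{message} (ligand {key})")
        self.key = key


@dataclass
class ProtonationRule:
    name: str
    pattern: Chem.Mol
    atom: int
    charge: int
    h_delta: int


def load_ph7_rules(path: str | Path | None = None) -> list[ProtonationRule]:
    """Load the versioned pH 7.0 protonation rule table.

    Each rule is a SMARTS pattern plus the formal-charge and hydrogen-count
    edit applied to one matched atom. Anionic rules (acid deprotonation)
    precede cationic rules (base protonation) in the table and are applied in
    table order; an atom is edited at most once.
    """
    if path is None:
        ref = resources.files("fragmint") / "data" / "ph7_rules.csv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for row in csv.DictReader(text.splitlines()):
        patt = Chem.MolFromSmarts(row["smarts"])
        if patt is None:
            raise ValueError(f"bad SMARTS in rule {row['name']}")
        rules.append(
            ProtonationRule(
                name=row["name"],
                pattern=patt,
                atom=int(row["atom"]),
                charge=int(row["charge"]),
                h_delta=int(row["h_delta"]),
            )
        )
    return rules


_RULES_CACHE: list[ProtonationRule] | None = None


def _default_rules() -> list[ProtonationRule]:
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = load_ph7_rules()
    return _RULES_CACHE


@dataclass
class StandardLigand:
    """A protonation-standardized molecule with an optional conformer ensemble.

    ``mol`` is the canonical hydrogen-implicit connection table; ``mol3d`` (set
    by :func:`generate_conformers`) carries explicit hydrogens and one RDKit
    conformer per retained ensemble member. ``energies`` are post-minimization
    MMFF94s energies (kcal/mol), one per conformer, sorted ascending.
    """

    mol: Chem.Mol
    key: str
    mol3d: Chem.Mol | None = None
    energies: list[float] = field(default_factory=list)

    @property
    def n_conformers(self) -> int:
        return 0 if self.mol3d is None else self.mol3d.GetNumConformers()

    def heavy_coords(self, conf_id: int = 0) -> np.ndarray:
        """Heavy-atom coordinates (Å) of one conformer, in atom order of mol3d."""
        if self.mol3d is None:
            raise ValueError("no conformers generated")
        conf = self.mol3d.GetConformer(conf_id)
        idx = [a.GetIdx() for a in self.mol3d.GetAtoms() if a.GetAtomicNum() > 1]
        return np.asarray(conf.GetPositions())[idx]


def apply_ph7_rules(mol: Chem.Mol, rules: Sequence[ProtonationRule] | None = None) -> Chem.Mol:
    """Apply the pH 7.0 charge rules, editing each atom at most once."""
    if rules is None:
        rules = _default_rules()
    mol = Chem.Mol(mol)
    edited: set[int] = set()
    for rule in rules:
        for match in mol.GetSubstructMatches(rule.pattern):
            idx = match[rule.atom]
            atom = mol.GetAtomWithIdx(idx)
            if idx in edited or atom.GetFormalCharge() != 0:
                continue
            n_h = atom.GetTotalNumHs()
            if rule.h_delta < 0 and n_h == 0:
                continue
            atom.SetFormalCharge(rule.charge)
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(max(n_h + rule.h_delta, 0))
            edited.add(idx)
    Chem.SanitizeMol(mol)
    return mol


def standardize_ligand(
    raw: Chem.Mol | str, rules: Sequence[ProtonationRule] | None = None
) -> StandardLigand:
    """Standardize a molecule: strip salts, set pH 7 charges, compute identity key.

    Parameters
    ----------
    raw:
        An RDKit molecule or a SMILES string.

    Raises
    ------
    LigandParseError
        If the input cannot be parsed or sanitized.
    EmptyMoleculeError
        If nothing survives salt stripping.
    """
    if isinstance(raw, str):
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            raise LigandParseError(f"unparsable SMILES: {raw!r}")
    else:
        mol = Chem.Mol(raw)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - rdkit raises various types
            raise LigandParseError(str(exc)) from exc
    mol = rdMolStandardize.Cleanup(mol)
    if mol.GetNumAtoms() == 0:
        raise EmptyMoleculeError("empty molecule")
    chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
    mol = chooser.choose(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise EmptyMoleculeError("no organic component after salt stripping")
    # Cleanup may have neutralized or left prior charges; re-derive from rules
    # on the uncharged parent so the rule table is the single authority.
    uncharger = rdMolStandardize.Uncharger()
    mol = uncharger.uncharge(mol)
    mol = apply_ph7_rules(mol, rules)
    key = Chem.MolToInchiKey(mol)
    return StandardLigand(mol=mol, key=key)


def _heavy_rms(mol_h: Chem.Mol, heavy: Chem.Mol, i: int, j: int) -> float:
    """Symmetry-aware best heavy-atom RMSD between conformers i and j."""
    return rdMolAlign.GetBestRMS(heavy, heavy, prbId=i, refId=j)


def prune_conformers(
    mol_h: Chem.Mol, energies: Sequence[float], rmsd_threshold: float = 0.5
) -> tuple[Chem.Mol, list[float]]:
    """Greedy energy-ordered pruning: keep conformers pairwise >= threshold apart.

    Returns a new molecule whose conformers are renumbered 0..k-1 in ascending
    energy order, plus the matching energy list.
    """
    heavy = Chem.RemoveHs(Chem.Mol(mol_h))
    order = np.argsort(energies, kind="stable")
    kept: list[int] = []
    for ci in order:
        ok = True
        for cj in kept:
            if _heavy_rms(mol_h, heavy, int(ci), int(cj)) < rmsd_threshold:
                ok = False
                break
        if ok:
            kept.append(int(ci))
    out = Chem.Mol(mol_h)
    out.RemoveAllConformers()
    for ci in kept:
        conf = Chem.Conformer(mol_h.GetConformer(ci))
        out.AddConformer(conf, assignId=True)
    return out, [float(energies[ci]) for ci in kept]


def generate_conformers(
    ligand: StandardLigand,
    n_requested: int = 5,
    seed: int = 42,
    n_overgenerate: int | None = None,
    prune_rmsd: float = 0.5,
    max_minimize_iters: int = 500,
) -> StandardLigand:
    """Populate the conformer ensemble of a standardized ligand.

    Embeds ``n_overgenerate`` conformers (default ``max(4 * n_requested, 20)``)
    with ETKDGv2 at a fixed seed, minimizes each with MMFF94s, prunes by
    heavy-atom RMSD, and keeps the ``n_requested`` lowest-energy survivors.
    Embedding is retried up to 3 times with offset seeds before raising
    :class:`ConformerGenerationError`.
    """
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")
    if n_overgenerate is None:
        n_overgenerate = max(4 * n_requested, 20)
    mol_h = Chem.AddHs(ligand.mol)
    params = AllChem.ETKDGv2()
    params.randomSeed = seed
    params.numThreads = 1
    conf_ids: list[int] = []
    for attempt in range(3):
        params.randomSeed = seed + 1000 * attempt
        conf_ids = list(AllChem.EmbedMultipleConfs(mol_h, numConfs=n_overgenerate, params=params))
        if conf_ids:
            break
    if not conf_ids:
        raise ConformerGenerationError(ligand.key)

    props = AllChem.MMFFGetMoleculeProperties(mol_h, mmffVariant="MMFF94s")
    energies = []
    for cid in conf_ids:
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol_h, props, confId=cid)
            ff.Minimize(maxIts=max_minimize_iters)
            energies.append(ff.CalcEnergy())
        else:  # MMFF typing failure (exotic atoms): keep unminimized, rank by 0
            energies.append(0.0)

    pruned, kept_energies = prune_conformers(mol_h, energies, prune_rmsd)
    if pruned.GetNumConformers() > n_requested:
        out = Chem.Mol(pruned)
        out.RemoveAllConformers()
        for cid in range(n_requested):
            out.AddConformer(Chem.Conformer(pruned.GetConformer(cid)), assignId=True)
        pruned, kept_energies = out, kept_energies[:n_requested]
    ligand.mol3d = pruned
    ligand.energies = kept_energies
    return ligand


def read_smiles(path: str | Path, column: str = "smiles") -> list[StandardLigand]:
    """Read ligands from a SMILES file (one per line) or a CSV with a smiles column."""
    path = Path(path)
    out = []
    if path.suffix.lower() == ".csv":
        import pandas as pd

        for smi in pd.read_csv(path)[column]:
            out.append(standardize_ligand(str(smi)))
    else:
        for line in path.read_text().splitlines():
            line = line.strip().split()[0] if line.strip() else ""
            if line:
                out.append(standardize_ligand(line))
    return out


def write_conformers_sdf(ligands: Iterable[StandardLigand], path: str | Path) -> None:
    """Write multi-conformer SDF with identity key and MMFF94s energy as SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for lig in ligands:
            if lig.mol3d is None:
                continue
            for cid in range(lig.mol3d.GetNumConformers()):
                mol = Chem.Mol(lig.mol3d)
                mol.SetProp("identity_key", lig.key)
                mol.SetProp("conformer_id", str(cid))
                mol.SetProp("mmff94s_energy", f"{lig.energies[cid]:.4f}")
                writer.write(mol, confId=cid)
    finally:
        writer.close()
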