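"""Template-pool management and 2D-similarity template selection.

A query ligand with known activity but no crystal structure is matched against
the pool of crystallographic ligands of the same protein. The top-k templates
(default 3) whose radius-2 circular-fingerprint Tanimoto strictly exceeds the
threshold (default 0.3) are carried into 3D alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from fragmint.chemprep import StandardLigand

_FP_GENERATORS: dict[int, object] = {}


def _fp_generator(n_bits: int):
    if n_bits not in _FP_GENERATORS:
        _FP_GENERATORS[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=n_bits
        )
    return _FP_GENERATORS[n_bits]


def morgan_fingerprint(mol: Chem.Mol, n_bits: int = 2048):
    """Radius-2 circular fingerprint folded to ``n_bits`` bits."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    return _fp_generator(n_bits).GetFingerprint(mol)


def tanimoto2d(a: Chem.Mol, b: Chem.Mol, n_bits: int = 2048) -> float:
    """2D Tanimoto similarity on radius-2 circular fingerprints."""
    return float(
        DataStructs.TanimotoSimilarity(
            morgan_fingerprint(a, n_bits), morgan_fingerprint(b, n_bits)
        )
    )


@dataclass
class TemplateEntry:
    """A crystallographic ligand pose available as an alignment template."""

    ligand: StandardLigand  # mol3d holds the crystal pose as conformer 0
    structure_id: str
    pocket_ref: str | None = None

    @property
    def key(self) -> str:
        return self.ligand.key


@dataclass
class TemplatePool:
    """All crystallographic ligands bound to one protein."""

    protein_id: str
    entries: list[TemplateEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.ligand.mol3d is None or e.ligand.mol3d.GetNumConformers() == 0:
                raise ValueError(f"template {e.key}/{e.structure_id} has no 3D pose")
            pair = (e.key, e.structure_id)
            if pair in seen:
                raise ValueError(f"duplicate template entry {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TemplateMatch:
    entry: TemplateEntry
    similarity2d: float


def select_templates(
    query: StandardLigand,
    pool: TemplatePool,
    k: int = 3,
    threshold: float = 0.3,
    n_bits: int = 2048,
) -> list[TemplateMatch]:
    """Top-k templates strictly above the Tanimoto threshold.

    Sorted by similarity descending; ties broken by source structure id
    ascending so the result is independent of pool order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qfp = morgan_fingerprint(query.mol, n_bits)
    scored = []
    for entry in pool.entries:
        sim = float(
            DataStructs.TanimotoSimilarity(qfp, morgan_fingerprint(entry.ligand.mol, n_bits))
        )
        if sim > threshold:
            scored.append(TemplateMatch(entry, sim))
    scored.sort(key=lambda m: (-m.similarity2d, m.entry.structure_id, m.entry.key))
    return scored[:k]


def exclude_self(pool: TemplatePool, query_key: str) -> TemplatePool:
    """Pool with every entry matching the query's identity key removed."""
    return TemplatePool(
        protein_id=pool.protein_id,
        entries=[e for e in pool.entries if e.key != query_key],
    )


def write_pool(pool: TemplatePool, directory: str | Path) -> None:
    """Serialize a pool as one SDF per entry plus a CSV index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, entry in enumerate(pool.entries):
        sdf_name = f"template_{i:04d}.sdf"
        writer = Chem.SDWriter(str(directory / sdf_name))
        mol = Chem.Mol(entry.ligand.mol3d)
        mol.SetProp("identity_key", entry.key)
        mol.SetProp("structure_id", entry.structure_id)
        writer.write(mol, confId=0)
        writer.close()
        rows.append(
            {
                "protein_id": pool.protein_id,
                "ligand_key": entry.key,
                "structure_id": entry.structure_id,
                "sdf": sdf_name,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "index.csv", index=False)


def read_pool(directory: str | Path) -> TemplatePool:
    """Load a pool serialized by :func:`write_pool`."""
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv")
    if index.empty:
        raise ValueError(f"empty pool index in {directory}")
    entries = []
    for _, row in index.iterrows():
        supplier = Chem.SDMolSupplier(str(directory / row["sdf"]), removeHs=False)
        mol3d = next(iter(supplier))
        if mol3d is None:
            raise ValueError(f"unreadable template SDF {row['sdf']}")
        heavy = Chem.RemoveHs(Chem.Mol(mol3d))
        lig = StandardLigand(mol=heavy, key=row["ligand_key"], mol3d=mol3d)
        entries.append(TemplateEntry(ligand=lig, structure_id=str(row["structure_id"])))
    return TemplatePool(protein_id=str(index.iloc[0]["protein_id"]), entries=entries)
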