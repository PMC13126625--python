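"""Active-ligand curation and the fragment–protein-environment repository.

Quantitative potencies (IC50/EC50/Ki/Kd) are converted to pAct = −log10(molar)
and records with pAct ≥ 5.0 (≤ 10 µM) or an explicit "active" label are kept.
Fragment poses are organized into unique (fragment key, protein id) pairs with
their contact-residue environments, supporting frequency comparison against a
crystal-derived fragment set, Murcko-scaffold analysis, and protein-family
enrichment.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from fragmint.chemprep import LigandParseError, standardize_ligand
from fragmint.fragmenter import FragmentPose, write_fragments_sdf
from fragmint.refine import PocketModel

QUANTITATIVE_TYPES = {"IC50", "EC50", "KI", "KD"}


@dataclass
class ActivityRecord:
    """One ligand–protein activity measurement."""

    smiles: str
    protein_id: str
    activity_type: str  # IC50/EC50/Ki/Kd or a qualitative label
    value_nm: float | None = None  # nM for quantitative records
    qualifier: str | None = None  # e.g. "active"/"inactive"
    ligand_key: str | None = None

    @property
    def is_quantitative(self) -> bool:
        return self.activity_type.upper() in QUANTITATIVE_TYPES and self.value_nm is not None

    @property
    def pact(self) -> float | None:
        if not self.is_quantitative:
            return None
        if self.value_nm <= 0:
            return None
        return float(-np.log10(self.value_nm * 1e-9))


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read an activity table: smiles, protein_id, activity_type, value_nM or qualifier."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        value = row.get("value_nM")
        records.append(
            ActivityRecord(
                smiles=str(row["smiles"]),
                protein_id=str(row["protein_id"]),
                activity_type=str(row["activity_type"]),
                value_nm=None if pd.isna(value) else float(value),
                qualifier=None if pd.isna(row.get("qualifier")) else str(row["qualifier"]),
            )
        )
    return records


def curate_actives(
    records: list[ActivityRecord], threshold: float = 5.0
) -> tuple[list[ActivityRecord], list[str]]:
    """Keep active binders; deduplicate by (ligand key, protein) keeping max pAct.

    A record is active if its pAct ≥ threshold, or it carries an explicit
    "active" qualitative label. Malformed records (unparsable SMILES,
    non-positive values) go to the rejection log rather than failing the run.
    """
    rejects: list[str] = []
    kept: dict[tuple[str, str], ActivityRecord] = {}
    for rec in records:
        try:
            std = standardize_ligand(rec.smiles)
        except (LigandParseError, ValueError) as exc:
            rejects.append(f"{rec.smiles}: {exc}")
            continue
        rec.ligand_key = std.key
        if rec.is_quantitative:
            pact = rec.pact
            if pact is None:
                rejects.append(f"{rec.smiles}: non-positive activity value")
                continue
            if pact < threshold:
                continue
        elif not (rec.qualifier and rec.qualifier.strip().lower() == "active"):
            continue
        dk = (std.key, rec.protein_id)
        prev = kept.get(dk)
        if prev is None:
            kept[dk] = rec
        else:
            prev_pact = prev.pact if prev.is_quantitative else None
            this_pact = rec.pact if rec.is_quantitative else None
            if (this_pact or -np.inf) > (prev_pact or -np.inf):
                kept[dk] = rec
    return list(kept.values()), rejects


@dataclass
class FragmentEnvironmentPair:
    """A unique (fragment, protein) pair with its contact-residue environment."""

    fragment_key: str
    protein_id: str
    contact_residues: frozenset[str]
    provenance: list[dict] = field(default_factory=list)  # parent ligand, pose, cs
    fingerprint: frozenset | None = None  # set of (residue, interaction type)
    representative: FragmentPose | None = None


def contact_residues(
    frag: FragmentPose, pocket: PocketModel, cutoff: float = 5.0
) -> frozenset[str]:
    """Residues with any heavy atom within ``cutoff`` Å of any fragment heavy atom."""
    coords = frag.heavy_coords()
    d = np.linalg.norm(pocket.coords[:, None, :] - coords[None, :, :], axis=-1)
    hit = d.min(axis=1) <= cutoff
    return frozenset(pocket.residue_labels()[hit])


def build_pairs(
    fragments: list[FragmentPose],
    pocket: PocketModel,
    protein_id: str,
    contact_cutoff: float = 5.0,
    cs_by_pose: dict[str, float] | None = None,
) -> tuple[list[FragmentEnvironmentPair], list[str]]:
    """Assemble unique fragment–environment pairs for one protein.

    Fragments with zero contacts are discarded; fragments more than 20 Å from
    every protein atom indicate a frame mismatch and are logged as warnings.
    """
    warnings: list[str] = []
    pairs: dict[tuple[str, str], FragmentEnvironmentPair] = {}
    for frag in fragments:
        coords = frag.heavy_coords()
        dmin = float(
            np.linalg.norm(pocket.coords[:, None, :] - coords[None, :, :], axis=-1).min()
        )
        if dmin > 20.0:
            warnings.append(
                f"fragment {frag.key} is {dmin:.1f} Å from the protein (frame mismatch?); discarded"
            )
            continue
        residues = contact_residues(frag, pocket, contact_cutoff)
        if not residues:
            continue
        pk = (frag.key, protein_id)
        prov = {
            "parent_key": frag.parent_key,
            "pose_id": frag.parent_pose_id,
            "cs": None if cs_by_pose is None else cs_by_pose.get(frag.parent_pose_id),
        }
        if pk in pairs:
            pairs[pk].provenance.append(prov)
            pairs[pk].contact_residues = pairs[pk].contact_residues | residues
        else:
            pairs[pk] = FragmentEnvironmentPair(
                fragment_key=frag.key,
                protein_id=protein_id,
                contact_residues=residues,
                provenance=[prov],
                representative=frag,
            )
    return list(pairs.values()), warnings


def murcko_scaffold(mol: Chem.Mol) -> Chem.Mol | None:
    """Ring systems plus linkers with side chains removed; None for acyclic input."""
    if mol.GetNumAtoms() == 0:
        return None
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return scaffold


def scaffold_key(mol: Chem.Mol) -> str | None:
    s = murcko_scaffold(mol)
    return None if s is None else Chem.MolToSmiles(s)


def frequency_compare(set_a: Counter | dict, set_b: Counter | dict) -> pd.DataFrame:
    """Full outer join of two fragment (or scaffold) multisets on key.

    Columns: key, count_a, count_b, in_a, in_b, shared, exclusive_a,
    exclusive_b. The frame carries two attrs: ``shared_keys`` and
    ``fraction_more_frequent_in_a`` (fraction of all keys whose count is
    strictly higher in A).
    """
    a, b = Counter(set_a), Counter(set_b)
    keys = sorted(set(a) | set(b))
    df = pd.DataFrame(
        {
            "key": keys,
            "count_a": [a.get(k, 0) for k in keys],
            "count_b": [b.get(k, 0) for k in keys],
        }
    )
    df["in_a"] = df["count_a"] > 0
    df["in_b"] = df["count_b"] > 0
    df["shared"] = df["in_a"] & df["in_b"]
    df["exclusive_a"] = df["in_a"] & ~df["in_b"]
    df["exclusive_b"] = df["in_b"] & ~df["in_a"]
    df.attrs["shared_keys"] = int(df["shared"].sum())
    df.attrs["fraction_more_frequent_in_a"] = (
        float((df["count_a"] > df["count_b"]).mean()) if len(df) else 0.0
    )
    return df


def family_enrichment(
    pairs: list[FragmentEnvironmentPair],
    families: dict[str, str],
    scaffold_of_fragment: dict[str, str | None],
) -> pd.DataFrame:
    """Per-family Murcko-scaffold counts with family-exclusive flags.

    ``scaffold_of_fragment`` maps fragment key → scaffold SMILES (None for
    acyclic fragments, which are skipped). Proteins missing from the family
    map fall into "other". Sorted by (family, count desc, scaffold asc).
    """
    rows = []
    for pair in pairs:
        scaffold = scaffold_of_fragment.get(pair.fragment_key)
        if scaffold is None:
            continue
        rows.append({"family": families.get(pair.protein_id, "other"), "scaffold": scaffold})
    if not rows:
        return pd.DataFrame(columns=["family", "scaffold", "count", "exclusive"])
    df = pd.DataFrame(rows)
    counts = df.groupby(["family", "scaffold"]).size().reset_index(name="count")
    n_families = counts.groupby("scaffold")["family"].transform("nunique")
    counts["exclusive"] = n_families == 1
    return counts.sort_values(
        ["family", "count", "scaffold"], ascending=[True, False, True]
    ).reset_index(drop=True)


def read_family_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["protein_id"].astype(str), df["family"].astype(str)))


def write_repository(
    pairs: list[FragmentEnvironmentPair],
    fragments: list[FragmentPose],
    directory: str | Path,
) -> None:
    """Write {fragments.sdf, pairs.csv, manifest.json} atomically (tmp + rename)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tmp_sdf = directory / ".fragments.sdf.tmp"
    write_fragments_sdf(fragments, tmp_sdf)
    rows = [
        {
            "fragment_key": p.fragment_key,
            "protein_id": p.protein_id,
            "contact_residues": ";".join(sorted(p.contact_residues)),
            "n_provenance": len(p.provenance),
            "best_cs": max(
                (pr["cs"] for pr in p.provenance if pr.get("cs") is not None), default=None
            ),
        }
        for p in pairs
    ]
    tmp_csv = directory / ".pairs.csv.tmp"
    pd.DataFrame(rows).to_csv(tmp_csv, index=False)
    manifest = {
        "n_pairs": len(pairs),
        "n_fragment_instances": len(fragments),
        "n_unique_fragments": len({f.key for f in fragments}),
        "files": ["fragments.sdf", "pairs.csv"],
    }
    tmp_manifest = directory / ".manifest.json.tmp"
    tmp_manifest.write_text(json.dumps(manifest, indent=2))
    tmp_sdf.rename(directory / "fragments.sdf")
    tmp_csv.rename(directory / "pairs.csv")
    tmp_manifest.rename(directory / "manifest.json")
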