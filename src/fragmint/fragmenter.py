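"""Exhaustive BRICS decomposition of posed ligands into 3D-annotated fragments.

"Every possible substructure derivable from the disconnection rules" is
formalized as every connected union of minimal BRICS fragments — equivalently,
cut any subset of cleavable bonds and keep each resulting connected piece.
The minimal fragments form a graph whose edges are the cleaved bonds; the
fragments of a molecule are exactly the connected induced subgraphs of that
graph (the whole molecule included). Fragment heavy atoms inherit their
parent-pose coordinates unchanged. Fragment-likeness filters: MW ≤ 300 Da,
HBD ≤ 3, HBA ≤ 6, 1 ≤ rings ≤ 4, rotatable bonds ≤ 5, computed on the
hydrogen-capped fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS, Descriptors, Lipinski, rdMolDescriptors


@dataclass
class FragmentPose:
    """A fragment with coordinates inherited from its parent pose."""

    mol: Chem.Mol  # capped fragment with one conformer (inherited coordinates)
    key: str  # InChIKey of the hydrogen-capped fragment
    parent_key: str
    parent_pose_id: str
    atom_indices: tuple[int, ...]  # parent heavy-atom indices
    cut_bonds: tuple[int, ...]  # parent bond indices severed at the boundary
    # one (anchor xyz, outward unit direction) per severed boundary bond,
    # anchored at the fragment-side atom of the cut
    attachments: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = ()
    truncated: bool = False

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    def heavy_coords(self) -> np.ndarray:
        pos = np.asarray(self.mol.GetConformer().GetPositions())
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        return pos[idx]

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)


@dataclass
class FragmentProperties:
    mw: float
    hbd: int
    hba: int
    n_rings: int
    n_rotatable: int


def enumerate_cleavable_bonds(mol: Chem.Mol) -> list[int]:
    """Bond indices matching the BRICS environment rules (never ring bonds)."""
    bonds = []
    for (i, j), _labels in BRICS.FindBRICSBonds(mol):
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond is not None and not bond.IsInRing():
            bonds.append(bond.GetIdx())
    return sorted(set(bonds))


def _minimal_fragment_graph(mol: Chem.Mol, cleavable: list[int]):
    """Partition atoms into minimal fragments; edges are the cleaved bonds.

    Returns (atom→node map, node atom sets, edge list [(node_a, node_b, bond_idx)]).
    """
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cleave_set = set(cleavable)
    for bond in mol.GetBonds():
        if bond.GetIdx() in cleave_set:
            continue
        a, b = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
        if a != b:
            parent[a] = b
    roots = sorted({find(i) for i in range(n)})
    node_of_root = {r: k for k, r in enumerate(roots)}
    atom_node = [node_of_root[find(i)] for i in range(n)]
    node_atoms = [set() for _ in roots]
    for i, nd in enumerate(atom_node):
        node_atoms[nd].add(i)
    edges = []
    for bidx in cleavable:
        bond = mol.GetBondWithIdx(bidx)
        a, b = atom_node[bond.GetBeginAtomIdx()], atom_node[bond.GetEndAtomIdx()]
        edges.append((a, b, bidx))
    return atom_node, node_atoms, edges


def connected_subgraphs(
    n_nodes: int, edges: list[tuple[int, int]], max_size: int | None = None
) -> list[frozenset]:
    """All connected induced node subsets, each exactly once.

    Enumerates per seed node s the connected subsets whose minimum node is s,
    growing only through nodes > s.
    """
    adj: list[set] = [set() for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return _connected_subsets(n_nodes, adj, max_size)


def _connected_subsets(n_nodes: int, adj: list[set], max_size: int | None):
    """Every connected induced subset exactly once (min-node-as-seed scheme)."""
    out: list[frozenset] = []
    for s in range(n_nodes):
        # BFS-style enumeration of connected subsets with minimum node s
        stack = [(frozenset([s]), frozenset(c for c in adj[s] if c > s))]
        seen = set()
        while stack:
            subset, frontier = stack.pop()
            if subset in seen:
                continue
            seen.add(subset)
            out.append(subset)
            if max_size is not None and len(subset) >= max_size:
                continue
            for c in sorted(frontier):
                new_sub = subset | {c}
                if new_sub in seen:
                    continue
                new_frontier = (frontier | frozenset(x for x in adj[c] if x > s)) - new_sub
                stack.append((new_sub, new_frontier))
    return out


def _extract_fragment(
    mol: Chem.Mol, atom_set: set[int], boundary_bonds: list[int]
) -> tuple[Chem.Mol, tuple[int, ...]]:
    """Capped submolecule on ``atom_set`` with inherited coordinates.

    Boundary bonds become hydrogen caps placed along the severed bond vector at
    a 1.0 Å offset so the capped fragment still sanitizes and the heavy-atom
    coordinates stay bit-identical to the parent pose.
    """
    emol = Chem.RWMol(mol)
    remove = sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in atom_set), reverse=True)
    # convert boundary neighbors to explicit H count before deletion
    boundary_pairs = []
    for bidx in boundary_bonds:
        bond = mol.GetBondWithIdx(bidx)
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        inside, outside = (a, b) if a in atom_set else (b, a)
        boundary_pairs.append((inside, outside))
    for inside, _outside in boundary_pairs:
        atom = emol.GetAtomWithIdx(inside)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
    for idx in remove:
        emol.RemoveAtom(idx)
    frag = emol.GetMol()
    Chem.SanitizeMol(frag)
    old_order = sorted(atom_set)
    if mol.GetNumConformers() > 0:
        conf = Chem.Conformer(frag.GetNumAtoms())
        parent_conf = mol.GetConformer()
        for new_idx, old_idx in enumerate(old_order):
            conf.SetAtomPosition(new_idx, parent_conf.GetAtomPosition(old_idx))
        frag.AddConformer(conf, assignId=True)
    return frag, tuple(old_order)


def exhaustive_fragments(
    parent_mol: Chem.Mol,
    parent_key: str = "",
    parent_pose_id: str = "",
    enumeration_cap: int = 14,
    subgraph_limit: int = 8,
) -> list[FragmentPose]:
    """All connected unions of minimal BRICS fragments, coordinates inherited.

    Molecules with more than ``enumeration_cap`` cleavable bonds fall back to
    subgraphs of at most ``subgraph_limit`` minimal fragments; affected
    fragments carry ``truncated=True``.
    """
    mol = Chem.RemoveHs(Chem.Mol(parent_mol))
    cleavable = enumerate_cleavable_bonds(mol)
    truncated = len(cleavable) > enumeration_cap
    max_size = subgraph_limit if truncated else None
    _atom_node, node_atoms, edges = _minimal_fragment_graph(mol, cleavable)
    adj = [set() for _ in node_atoms]
    for a, b, _ in edges:
        adj[a].add(b)
        adj[b].add(a)
    subsets = _connected_subsets(len(node_atoms), adj, max_size)

    out = []
    for subset in subsets:
        atom_set = set().union(*(node_atoms[nd] for nd in subset))
        boundary = [
            bidx for a, b, bidx in edges if (a in subset) != (b in subset)
        ]
        frag, old_order = _extract_fragment(mol, atom_set, boundary)
        key = Chem.MolToInchiKey(frag)
        attachments = []
        if mol.GetNumConformers() > 0:
            pconf = mol.GetConformer()
            for bidx in sorted(boundary):
                bond = mol.GetBondWithIdx(bidx)
                a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                inside, outside = (a, b) if a in atom_set else (b, a)
                anchor = np.array(pconf.GetAtomPosition(inside))
                vec = np.array(pconf.GetAtomPosition(outside)) - anchor
                norm = np.linalg.norm(vec)
                if norm > 1e-9:
                    attachments.append((tuple(anchor), tuple(vec / norm)))
        out.append(
            FragmentPose(
                mol=frag,
                key=key,
                parent_key=parent_key,
                parent_pose_id=parent_pose_id,
                atom_indices=old_order,
                cut_bonds=tuple(sorted(boundary)),
                attachments=tuple(attachments),
                truncated=truncated,
            )
        )
    out.sort(key=lambda f: (len(f.atom_indices), f.atom_indices))
    return out


def fragment_properties(frag: FragmentPose | Chem.Mol) -> FragmentProperties:
    """Fragment-likeness descriptors of the hydrogen-capped fragment.

    Ring count is the smallest-set-of-smallest-rings count; rotatable bonds
    follow the strict definition (acyclic single bonds between two
    non-terminal heavy atoms, amide C–N excluded).
    """
    mol = frag.mol if isinstance(frag, FragmentPose) else frag
    return FragmentProperties(
        mw=float(Descriptors.MolWt(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        n_rings=int(rdMolDescriptors.CalcNumRings(mol)),
        n_rotatable=int(
            rdMolDescriptors.CalcNumRotatableBonds(
                mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
            )
        ),
    )


def passes_filters(props: FragmentProperties) -> bool:
    """MW ≤ 300 AND HBD ≤ 3 AND HBA ≤ 6 AND 1 ≤ rings ≤ 4 AND rot. bonds ≤ 5."""
    return (
        props.mw <= 300.0
        and props.hbd <= 3
        and props.hba <= 6
        and 1 <= props.n_rings <= 4
        and props.n_rotatable <= 5
    )


def filter_fragments(fragments: list[FragmentPose]) -> list[FragmentPose]:
    return [f for f in fragments if passes_filters(fragment_properties(f))]


def write_fragments_sdf(fragments: list[FragmentPose], path) -> None:
    """SDF with fragment key, parent provenance, properties and pass/fail tag."""
    writer = Chem.SDWriter(str(path))
    try:
        for f in fragments:
            mol = Chem.Mol(f.mol)
            props = fragment_properties(f)
            mol.SetProp("fragment_key", f.key)
            mol.SetProp("parent_key", f.parent_key)
            mol.SetProp("parent_pose_id", f.parent_pose_id)
            mol.SetProp("cut_bonds", ",".join(map(str, f.cut_bonds)))
            mol.SetProp("MW", f"{props.mw:.2f}")
            mol.SetProp("HBD", str(props.hbd))
            mol.SetProp("HBA", str(props.hba))
            mol.SetProp("NR", str(props.n_rings))
            mol.SetProp("NRB", str(props.n_rotatable))
            mol.SetProp("passes_filters", str(passes_filters(props)))
            writer.write(mol)
    finally:
        writer.close()
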