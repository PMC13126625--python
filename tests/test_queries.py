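"""Interaction fingerprints, bioisostere search, attachment vectors, hopping."""

import numpy as np
import pytest
from rdkit import Chem

from fragmint import queries
from fragmint.fragmenter import FragmentPose
from fragmint.library import FragmentEnvironmentPair
from tests.conftest import build_mol, ideal_benzene, make_pocket


def _his_ring_pocket(z: float = 0.0, res_id: int = 80):
    """Planar five-membered histidine ring centered at the origin."""
    ang = np.radians(90 + 72 * np.arange(5))
    coords = np.stack([1.16 * np.cos(ang), 1.16 * np.sin(ang), np.full(5, z)], axis=1)
    return make_pocket(
        [6, 7, 6, 6, 7],
        coords,
        res_names=["HIS"] * 5,
        atom_names=["CG", "ND1", "CD2", "CE1", "NE2"],
        res_ids=[res_id] * 5,
    )


def _water_ligand(o=(0.0, 0.0, 0.0)):
    mol = Chem.AddHs(Chem.MolFromSmiles("O"))
    conf = Chem.Conformer(3)
    conf.SetAtomPosition(0, tuple(float(x) for x in o))
    conf.SetAtomPosition(1, (o[0] + 0.96, o[1], o[2]))
    conf.SetAtomPosition(2, (o[0] - 0.24, o[1] + 0.93, o[2]))
    mol.AddConformer(conf)
    return mol


class TestInteractionFingerprint:
    def test_remote_ligand_has_empty_fingerprint(self):
        pocket = _his_ring_pocket()
        mol = ideal_benzene(z=50.0)
        assert queries.interaction_fingerprint(mol, pocket) == frozenset()

    def test_parallel_pi_stack_detected(self):
        """Benzene 3.8 Å above a parallel histidine ring."""
        pocket = _his_ring_pocket(z=0.0)
        mol = ideal_benzene(z=3.8)
        fp = queries.interaction_fingerprint(mol, pocket)
        assert ("HIS80.A", "PiStacking") in fp

    def test_tilted_ring_beyond_parallel_window_rejected(self):
        """A 45° tilt falls outside both the parallel and T-shaped windows."""
        pocket = _his_ring_pocket(z=0.0)
        mol = ideal_benzene()
        conf = mol.GetConformer()
        pos = np.asarray(conf.GetPositions())
        theta = np.radians(45)
        R = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )
        for i, p in enumerate(pos @ R.T + [0, 0, 3.8]):
            conf.SetAtomPosition(i, p.tolist())
        fp = queries.interaction_fingerprint(mol, pocket)
        assert ("HIS80.A", "PiStacking") not in fp

    def test_hbond_donor_near_linear_geometry(self):
        """Ligand hydroxyl 2.9 Å from a backbone carbonyl oxygen, O–H aimed
        straight at the acceptor."""
        mol = _water_ligand()
        pocket = make_pocket(
            [8], np.array([[2.9, 0.0, 0.0]]), res_names=["ALA"], atom_names=["O"], res_ids=[7]
        )
        fp = queries.interaction_fingerprint(mol, pocket)
        assert ("ALA7.A", "HBDonor") in fp

    def test_hbond_donor_bent_geometry_rejected(self):
        """Acceptor placed behind the donor: D–H···A angle far below 130°."""
        mol = _water_ligand()
        pocket = make_pocket(
            [8], np.array([[-2.0, -2.0, 0.0]]), res_names=["ALA"], atom_names=["O"], res_ids=[7]
        )
        fp = queries.interaction_fingerprint(mol, pocket)
        assert ("ALA7.A", "HBDonor") not in fp

    def test_ionic_contact_requires_opposite_charges(self):
        mol = Chem.MolFromSmiles("C[NH3+]")
        conf = Chem.Conformer(2)
        conf.SetAtomPosition(0, (0, 0, 0))
        conf.SetAtomPosition(1, (1.5, 0, 0))
        mol.AddConformer(conf)
        asp = make_pocket(
            [8], np.array([[4.5, 0, 0]]), res_names=["ASP"], atom_names=["OD1"], res_ids=[3]
        )
        lys = make_pocket(
            [7], np.array([[4.5, 0, 0]]), res_names=["LYS"], atom_names=["NZ"], res_ids=[3]
        )
        assert ("ASP3.A", "Ionic") in queries.interaction_fingerprint(mol, asp)
        assert ("LYS3.A", "Ionic") not in queries.interaction_fingerprint(mol, lys)

    def test_determinism_and_atom_order_invariance(self, toy, toy_pocket):
        mol = toy.template.mol3d
        fp1 = queries.interaction_fingerprint(mol, toy_pocket)
        renum = Chem.RenumberAtoms(mol, list(range(mol.GetNumAtoms()))[::-1])
        fp2 = queries.interaction_fingerprint(renum, toy_pocket)
        assert fp1 == fp2

    def test_csv_roundtrip(self, tmp_path):
        fp = frozenset({("HIS80.A", "PiStacking"), ("ASN75.A", "HBDonor")})
        queries.fingerprint_to_csv(fp, tmp_path / "fp.csv")
        assert queries.fingerprint_from_csv(tmp_path / "fp.csv") == fp


def _pair(key, protein="P1", fp=None, cs=0.9):
    return FragmentEnvironmentPair(
        fragment_key=key,
        protein_id=protein,
        contact_residues=frozenset({"GLY1.A"}),
        provenance=[{"parent_key": "L", "pose_id": "p", "cs": cs}],
        fingerprint=fp,
    )


class TestBioisostereSearch:
    REF = frozenset({("ASN75.A", "HBDonor"), ("HIS80.A", "PiStacking")})

    def test_self_match_in_both_modes(self):
        pairs = [_pair("F1", fp=self.REF)]
        for mode in ("strict", "superset"):
            assert len(queries.bioisostere_search(pairs, "P1", self.REF, mode)) == 1

    def test_empty_repo(self):
        assert queries.bioisostere_search([], "P1", self.REF) == []

    def test_planted_fingerprint_found_in_strict_mode(self):
        pairs = [
            _pair("MATCH", fp=self.REF),
            # extra interaction on a reference residue breaks strict equality
            _pair("EXTRA", fp=self.REF | {("HIS80.A", "Hydrophobic")}),
            _pair("MISS", fp=frozenset({("ASN75.A", "HBDonor")})),
        ]
        strict = queries.bioisostere_search(pairs, "P1", self.REF, "strict")
        assert [p.fragment_key for p in strict] == ["MATCH"]

    def test_strict_subset_of_superset(self):
        extra_elsewhere = self.REF | {("SER287.A", "Hydrophobic")}
        pairs = [
            _pair("A", fp=self.REF, cs=0.9),
            _pair("B", fp=extra_elsewhere, cs=0.8),
            _pair("C", fp=frozenset(), cs=0.7),
        ]
        strict = {p.fragment_key for p in queries.bioisostere_search(pairs, "P1", self.REF, "strict")}
        sup = {p.fragment_key for p in queries.bioisostere_search(pairs, "P1", self.REF, "superset")}
        assert strict <= sup

    def test_sorted_by_confidence(self):
        pairs = [_pair("LOW", fp=self.REF, cs=0.3), _pair("HIGH", fp=self.REF, cs=0.95)]
        hits = queries.bioisostere_search(pairs, "P1", self.REF, "superset")
        assert [p.fragment_key for p in hits] == ["HIGH", "LOW"]


def _toluene_reference():
    """Toluene with an ideal ring; atom 0 is the methyl substituent."""
    ang = np.radians(90 + 60 * np.arange(6))
    ring = np.stack([1.396 * np.cos(ang), 1.396 * np.sin(ang), np.zeros(6)], axis=1)
    methyl = ring[0] * (1 + 1.5 / 1.396)
    coords = np.vstack([methyl, ring])
    return build_mol("Cc1ccccc1", coords)


class TestAttachmentVectors:
    def test_whole_molecule_core_has_no_vectors(self):
        mol = _toluene_reference()
        assert queries.extract_attachment_vectors(mol, range(7)) == []

    def test_ring_core_has_one_methyl_vector(self):
        mol = _toluene_reference()
        vecs = queries.extract_attachment_vectors(mol, range(1, 7))
        assert len(vecs) == 1
        assert np.linalg.norm(vecs[0].direction) == pytest.approx(1.0, abs=1e-9)
        # points outward from the ring toward the methyl
        assert vecs[0].direction @ np.array([0.0, 1.0, 0.0]) > 0.99

    def test_disconnected_core_rejected(self):
        mol = _toluene_reference()
        with pytest.raises(ValueError):
            queries.extract_attachment_vectors(mol, [0, 3])


def _benzene_fragment(direction, anchor=None, shift=(0.0, 0.0, 0.0)):
    mol = ideal_benzene()
    conf = mol.GetConformer()
    pos = np.asarray(conf.GetPositions()) + np.asarray(shift)
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, p.tolist())
    if anchor is None:
        anchor = pos[0]
    return FragmentPose(
        mol=mol,
        key="BENZENE-FRAG",
        parent_key="L",
        parent_pose_id="p",
        atom_indices=tuple(range(6)),
        cut_bonds=(0,),
        attachments=((tuple(anchor), tuple(direction)),),
    )


class TestScaffoldHop:
    def _repo(self, frag):
        pair = _pair("BENZENE-FRAG", fp=frozenset())
        pair.representative = frag
        return [pair]

    def test_self_hop_perfect_match(self):
        ref = _toluene_reference()
        up = np.array([0.0, 1.0, 0.0])
        frag = _benzene_fragment(up)
        hits = queries.scaffold_hop(self._repo(frag), "P1", ref, range(1, 7))
        assert len(hits) == 1
        assert hits[0].shape_overlap == pytest.approx(1.0, abs=1e-6)
        assert hits[0].vector_deviation == pytest.approx(0.0, abs=1e-9)

    def test_translated_fragment_rejected_on_shape(self):
        ref = _toluene_reference()
        frag = _benzene_fragment(np.array([0.0, 1.0, 0.0]), shift=(10.0, 0, 0))
        assert queries.scaffold_hop(self._repo(frag), "P1", ref, range(1, 7)) == []

    def test_angle_tolerance_window(self):
        """Direction rotated 45°: rejected at θ=30°, accepted at θ=50°."""
        ref = _toluene_reference()
        theta = np.radians(45)
        rotated = np.array([np.sin(theta), np.cos(theta), 0.0])
        frag = _benzene_fragment(rotated)
        assert (
            queries.scaffold_hop(self._repo(frag), "P1", ref, range(1, 7), angle_tolerance=30.0)
            == []
        )
        hits = queries.scaffold_hop(
            self._repo(frag), "P1", ref, range(1, 7), angle_tolerance=50.0
        )
        assert len(hits) == 1

    def test_no_reference_vectors_raises(self):
        ref = _toluene_reference()
        frag = _benzene_fragment(np.array([0.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            queries.scaffold_hop(self._repo(frag), "P1", ref, range(7))

    def test_rigid_transform_invariance(self):
        """Rotating repo, reference and receptor together changes nothing."""
        ref = _toluene_reference()
        up = np.array([0.0, 1.0, 0.0])
        frag = _benzene_fragment(up)
        base = queries.scaffold_hop(self._repo(frag), "P1", ref, range(1, 7))

        theta = np.radians(33)
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        t = np.array([3.0, -2.0, 1.0])
        ref2 = Chem.Mol(ref)
        conf = ref2.GetConformer()
        for i, p in enumerate(np.asarray(conf.GetPositions()) @ R.T + t):
            conf.SetAtomPosition(i, p.tolist())
        frag2_mol = Chem.Mol(frag.mol)
        conf = frag2_mol.GetConformer()
        pos2 = np.asarray(conf.GetPositions()) @ R.T + t
        for i, p in enumerate(pos2):
            conf.SetAtomPosition(i, p.tolist())
        anchor2 = np.asarray(frag.attachments[0][0]) @ R.T + t
        dir2 = np.asarray(frag.attachments[0][1]) @ R.T
        frag2 = FragmentPose(
            mol=frag2_mol, key=frag.key, parent_key="L", parent_pose_id="p",
            atom_indices=frag.atom_indices, cut_bonds=frag.cut_bonds,
            attachments=((tuple(anchor2), tuple(dir2)),),
        )
        moved = queries.scaffold_hop(self._repo(frag2), "P1", ref2, range(1, 7))
        assert len(moved) == len(base) == 1
        assert moved[0].shape_overlap == pytest.approx(base[0].shape_overlap, abs=1e-6)
        assert moved[0].vector_deviation == pytest.approx(base[0].vector_deviation, abs=1e-6)


def test_assemble_molecule_rebuilds_valid_structure():
    ref = _toluene_reference()
    frag = _benzene_fragment(np.array([0.0, 1.0, 0.0]))
    mol = queries.assemble_molecule(ref, range(1, 7), frag, relax=False)
    assert mol is not None
    # benzene core + methyl substituent = toluene topology
    assert Chem.MolToSmiles(Chem.RemoveHs(mol)) == "Cc1ccccc1"
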