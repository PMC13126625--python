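"""Pose evaluation: superposition, symmetry RMSD, clustering, hotspots."""

import numpy as np
import pytest
from rdkit import Chem

from fragmint import fixtures, validation
from fragmint.fragmenter import FragmentPose
from tests.conftest import ideal_benzene


class TestBackboneSuperpose:
    def test_identity(self, toy):
        R, t, rmsd = validation.backbone_superpose(toy.receptor, toy.receptor)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_recovered(self, toy):
        import biotite.structure as struc

        moved = toy.receptor.copy()
        moved.coord = moved.coord + np.array([5.0, 0.0, 0.0])
        R, t, rmsd = validation.backbone_superpose(moved, toy.receptor)
        np.testing.assert_allclose(t, [-5.0, 0.0, 0.0], atol=1e-6)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_jittered_copy_fit_rmsd_matches_noise_scale(self, toy):
        rng = np.random.default_rng(9)
        sigma = 0.1
        moved = toy.receptor.copy()
        moved.coord = moved.coord + rng.normal(0, sigma, moved.coord.shape)
        _, _, rmsd = validation.backbone_superpose(moved, toy.receptor)
        # expected RMSD ≈ sigma * sqrt(3) before fitting, slightly less after
        assert 0.05 < rmsd < 0.3

    def test_too_few_matches_raises(self, toy):
        import biotite.structure as struc

        small = toy.receptor[toy.receptor.res_id <= 1]
        with pytest.raises(ValueError):
            validation.backbone_superpose(small, small)


def _rotated_benzene(angle_deg: float) -> Chem.Mol:
    mol = ideal_benzene()
    conf = mol.GetConformer()
    pos = np.asarray(conf.GetPositions())
    c = pos.mean(axis=0)
    th = np.radians(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    for i, p in enumerate((pos - c) @ R.T + c):
        conf.SetAtomPosition(i, p.tolist())
    return mol


class TestSymmetryRmsd:
    def test_identical_coordinates(self):
        mol = ideal_benzene()
        assert validation.symmetry_rmsd(mol, mol) == 0.0

    def test_benzene_sixty_degree_rotation_absorbed(self):
        assert validation.symmetry_rmsd(ideal_benzene(), _rotated_benzene(60.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_uniform_translation_closed_form(self):
        mol = ideal_benzene()
        moved = Chem.Mol(mol)
        conf = moved.GetConformer()
        for i, p in enumerate(np.asarray(conf.GetPositions()) + [1.0, 0.0, 0.0]):
            conf.SetAtomPosition(i, p.tolist())
        assert validation.symmetry_rmsd(mol, moved) == pytest.approx(1.0, abs=1e-9)

    def test_never_exceeds_naive_index_matched_rmsd(self):
        rng = np.random.default_rng(12)
        mol = ideal_benzene()
        base = np.asarray(mol.GetConformer().GetPositions())
        for _ in range(100):
            moved = Chem.Mol(mol)
            conf = moved.GetConformer()
            pert = base + rng.normal(0, 0.7, base.shape)
            for i, p in enumerate(pert):
                conf.SetAtomPosition(i, p.tolist())
            naive = float(np.sqrt(np.mean(np.sum((base - pert) ** 2, axis=1))))
            assert validation.symmetry_rmsd(mol, moved) <= naive + 1e-9

    def test_equality_for_asymmetric_molecule(self):
        mol = Chem.MolFromSmiles("CCO")
        conf = Chem.Conformer(3)
        for i in range(3):
            conf.SetAtomPosition(i, (1.4 * i, 0.0, 0.0))
        mol.AddConformer(conf)
        moved = Chem.Mol(mol)
        c = moved.GetConformer()
        pert = np.asarray(c.GetPositions()) + [[0.3, 0, 0], [0, 0.2, 0], [0, 0, 0.6]]
        for i, p in enumerate(pert):
            c.SetAtomPosition(i, p.tolist())
        naive = float(
            np.sqrt(np.mean(np.sum((np.asarray(conf.GetPositions()) - pert) ** 2, axis=1)))
        )
        assert validation.symmetry_rmsd(mol, moved) == pytest.approx(naive, abs=1e-12)

    def test_graph_mismatch_raises(self):
        with pytest.raises(validation.GraphMismatchError):
            validation.symmetry_rmsd(ideal_benzene(), Chem.MolFromSmiles("CCO"))


class TestClusterBindingSites:
    def test_single_tight_group(self):
        pts = np.random.default_rng(1).normal(0, 1.0, (10, 3))
        n, labels = validation.cluster_binding_sites(pts, 8.0)
        assert n == 1 and (labels == 0).all()

    def test_two_distant_groups(self):
        a = np.random.default_rng(2).normal(0, 1.0, (5, 3))
        b = a + [20.0, 0, 0]
        n, labels = validation.cluster_binding_sites(np.vstack([a, b]), 8.0)
        assert n == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_empty_input(self):
        n, labels = validation.cluster_binding_sites(np.empty((0, 3)), 8.0)
        assert n == 0 and len(labels) == 0


def _frag(smiles: str, offset) -> FragmentPose:
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, (offset[0] + 1.4 * i, offset[1], offset[2]))
    mol.AddConformer(conf)
    return FragmentPose(
        mol=mol, key=Chem.MolToInchiKey(mol), parent_key="L", parent_pose_id="p",
        atom_indices=tuple(range(mol.GetNumAtoms())), cut_bonds=(),
    )


class TestHotspotRecovery:
    def test_identical_sets_fully_recovered(self):
        frags = [_frag("c1ccccc1", (0, 0, 0)), _frag("CCO", (10, 0, 0))]
        fraction, table = validation.hotspot_recovery(frags, frags, cutoff=2.0)
        assert fraction == 1.0
        assert (table["min_centroid_distance"] == 0.0).all()
        assert (table["max_similarity"] == 1.0).all()

    def test_distant_fragment_not_recovered(self):
        pred = [_frag("c1ccccc1", (0, 0, 0))]
        ref = [_frag("c1ccccc1", (5.0, 0, 0))]
        fraction, _ = validation.hotspot_recovery(pred, ref, cutoff=2.0)
        assert fraction == 0.0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        smiles = ["c1ccccc1", "CCO", "CCN", "c1ccncc1"]
        pred = [_frag(s, rng.uniform(-5, 5, 3)) for s in smiles]
        ref = [_frag(s, rng.uniform(-5, 5, 3)) for s in ["CCO", "CCC", "c1ccccc1"]]
        fraction, table = validation.hotspot_recovery(pred, ref, cutoff=2.0)
        from fragmint.templates import tanimoto2d

        for row, pf in zip(table.itertuples(), pred):
            dists = [np.linalg.norm(pf.centroid() - rf.centroid()) for rf in ref]
            sims = [tanimoto2d(pf.mol, rf.mol) for rf in ref]
            assert row.min_centroid_distance == pytest.approx(min(dists))
            assert row.max_similarity == pytest.approx(max(sims))

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            validation.hotspot_recovery([_frag("CCO", (0, 0, 0))], [], 2.0)


class TestCumulativeCurve:
    def test_monotone_and_reaches_hundred(self):
        curve = validation.cumulative_curve([0.5, 1.2, 3.7, 0.9, 2.2])
        pct = curve["pct_leq"].to_numpy()
        assert (np.diff(pct) >= -1e-12).all()
        assert pct[-1] == 100.0


def test_leave_one_out_aggregate_equals_mean_of_flags(toy):
    """Spec definition check on a no-template edge case table."""
    from fragmint.config import PipelineConfig
    from fragmint.templates import TemplatePool
    from fragmint.validation import BenchmarkEntry

    # pools containing only the query itself -> empty after self-exclusion
    entries = []
    for i, q in enumerate(toy.queries[:2]):
        pool = TemplatePool(protein_id="TOY00001", entries=[
            e for e in toy.template_pool(include_queries=True).entries if e.key == q.key
        ])
        entries.append(BenchmarkEntry(entry_id=f"e{i}", query=q, pool=pool))
    res = validation.run_leave_one_out(entries, PipelineConfig(), empty_pool_convention="count-as-failure")
    assert res.n_no_template == 2
    assert res.success_rate == 0.0
    res2 = validation.run_leave_one_out(entries, PipelineConfig(), empty_pool_convention="exclude")
    assert np.isnan(res2.success_rate)
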