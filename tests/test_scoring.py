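"""Pose metrics, normalization, confidence fusion and weight optimization."""

import numpy as np
import pytest
from rdkit import Chem

from fragmint import scoring
from fragmint.config import PipelineConfig, ScoringWeights
from tests.conftest import empty_pocket, make_pocket, single_atom_mol


class TestVinaTypeScore:
    def test_no_pocket_contact_gives_zero_with_flag(self):
        mol = single_atom_mol("C")
        pocket = make_pocket([6], np.array([[50.0, 0, 0]]))
        res = scoring.vina_type_score(mol, pocket)
        assert res.no_contact and res.value == 0.0
        assert all(v == 0.0 for v in res.terms.values())

    def test_first_gaussian_maximum_at_zero_surface_distance(self):
        """One C–C pair at surface distance 0: gauss1 term hits its closed-form
        maximum exp(0) = 1."""
        r = 2 * 1.9  # sum of carbon XS radii
        mol = single_atom_mol("C")
        pocket = make_pocket([6], np.array([[r, 0.0, 0.0]]))
        res = scoring.vina_type_score(mol, pocket)
        assert res.terms["gauss1"] == pytest.approx(1.0, abs=1e-12)
        assert res.terms["repulsion"] == 0.0

    def test_overlapping_atoms_have_positive_repulsion(self):
        mol = single_atom_mol("C")
        pocket = make_pocket([6], np.array([[0.5, 0.0, 0.0]]))
        res = scoring.vina_type_score(mol, pocket)
        assert res.terms["repulsion"] > 0

    def test_hbond_pair_requires_donor_acceptor_typing(self):
        # ligand hydroxyl O (donor/acceptor) near backbone O (acceptor)
        mol = Chem.AddHs(Chem.MolFromSmiles("O"))
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, (0.2 * i, 0.0, 0.0))
        mol.AddConformer(conf)
        pocket_acc = make_pocket([8], np.array([[3.0, 0, 0]]), atom_names=["O"])
        pocket_c = make_pocket([6], np.array([[3.0, 0, 0]]), atom_names=["CA"])
        assert scoring.vina_type_score(mol, pocket_acc).terms["hbond"] > 0
        assert scoring.vina_type_score(mol, pocket_c).terms["hbond"] == 0.0


class TestECIF:
    def test_empty_pocket_gives_zero_vector(self):
        feats = scoring.ecif_features(single_atom_mol("C"), empty_pocket())
        assert feats.sum() == 0

    def test_single_pair_populates_exactly_one_bin(self):
        """Brute-force oracle: one C(ligand)–C(protein) pair at 5 Å with a 6 Å
        cutoff yields a single count."""
        mol = single_atom_mol("C")
        pocket = make_pocket([6], np.array([[5.0, 0, 0]]))
        feats = scoring.ecif_features(mol, pocket, cutoff=6.0)
        assert feats.sum() == 1
        vocab = scoring.ECIFVocabulary()
        idx = int(np.nonzero(feats)[0][0])
        assert vocab.labels()[idx].startswith("C-C;")

    def test_cutoff_monotonicity(self):
        mol = Chem.MolFromSmiles("CCO")
        conf = Chem.Conformer(3)
        for i in range(3):
            conf.SetAtomPosition(i, (1.4 * i, 0.0, 0.0))
        mol.AddConformer(conf)
        rng = np.random.default_rng(4)
        pocket = make_pocket([6] * 10, rng.uniform(-6, 6, (10, 3)))
        f_small = scoring.ecif_features(mol, pocket, cutoff=4.0)
        f_large = scoring.ecif_features(mol, pocket, cutoff=6.0)
        assert (f_small <= f_large).all()

    def test_bad_cutoff_raises(self):
        with pytest.raises(ValueError):
            scoring.ecif_features(single_atom_mol("C"), empty_pocket(), cutoff=0.0)


class TestIntSim:
    def test_missing_estimator_raises_with_instruction(self):
        with pytest.raises(scoring.EstimatorMissingError):
            scoring.int_sim(single_atom_mol("C"), empty_pocket(), None)

    def test_sum_estimator_returns_total_pair_count(self):
        mol = single_atom_mol("C")
        pocket = make_pocket([6, 7], np.array([[4.0, 0, 0], [0, 4.0, 0]]))
        value = scoring.int_sim(mol, pocket, estimator=lambda f: float(f.sum()))
        assert value == 2.0

    def test_determinism(self):
        est = scoring.fit_synthetic_estimator(seed=1)
        mol = single_atom_mol("C")
        pocket = make_pocket([6], np.array([[4.0, 0, 0]]))
        assert scoring.int_sim(mol, pocket, est) == scoring.int_sim(mol, pocket, est)


class TestNormalization:
    def test_endpoints_and_clamping(self):
        cfg = PipelineConfig()
        worst, best = cfg.dock_norm_range
        assert scoring.normalize_metrics(0, 0, worst, 5.0, cfg).dock_norm == 0.0
        assert scoring.normalize_metrics(0, 0, best, 5.0, cfg).dock_norm == 1.0
        assert scoring.normalize_metrics(0, 0, best - 10, 5.0, cfg).dock_norm == 1.0
        assert scoring.normalize_metrics(0, 0, worst + 10, 5.0, cfg).dock_norm == 0.0

    def test_zero_width_range_raises(self):
        cfg = PipelineConfig(dock_norm_range=(1.0, 1.0))
        with pytest.raises(ValueError):
            scoring.normalize_metrics(0, 0, 0.5, 5.0, cfg)


class TestConfidenceScore:
    def test_linearity_in_metrics(self):
        w = ScoringWeights()
        rng = np.random.default_rng(0)
        m = rng.uniform(size=4)
        for lam in (0.0, 0.25, 1.0):
            s = scoring.PoseScore(
                sim2d=lam * m[0], sim3d=lam * m[1], dock_norm=lam * m[2], int_sim_norm=lam * m[3]
            )
            full = scoring.PoseScore(sim2d=m[0], sim3d=m[1], dock_norm=m[2], int_sim_norm=m[3])
            assert scoring.confidence_score(s, w) == pytest.approx(
                lam * scoring.confidence_score(full, w), abs=1e-12
            )


class TestOptimizeWeights:
    def _planted(self, n=200, noise=0.0, seed=3):
        from fragmint.fixtures import make_scored_dataset

        df = make_scored_dataset(n=n, noise_sd=noise, seed=seed)
        X = df[["sim2d", "sim3d", "dock_norm", "int_sim_norm"]].to_numpy()
        return X, df["success"].to_numpy()

    def test_single_class_raises(self):
        X = np.random.default_rng(0).uniform(size=(60, 4))
        with pytest.raises(ValueError):
            scoring.optimize_weights((X, np.ones(60, bool)))

    def test_signal_metric_dominates(self):
        """success ⇔ sim3d > 0.5 with pure-noise other metrics ⇒ β exceeds
        α, γ, δ."""
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(300, 4))
        y = X[:, 1] > 0.5
        res = scoring.optimize_weights((X, y), grid_step=0.054)
        a, b, g, d = res.weights.as_array()
        assert b > a and b > g and b > d

    def test_separable_data_reaches_f1_one(self):
        X, y = self._planted(noise=0.0)
        res = scoring.optimize_weights((X, y), grid_step=0.054)
        assert res.f1 == pytest.approx(1.0)

    def test_planted_weight_recovery_direction(self):
        X, y = self._planted(noise=0.0)
        res = scoring.optimize_weights((X, y), grid_step=0.027)
        w = res.weights.as_array()
        planted = ScoringWeights().as_array()
        cosine = w @ planted / (np.linalg.norm(w) * np.linalg.norm(planted))
        assert cosine >= 0.95
        assert np.abs(w - planted).max() <= 0.027 + 1e-9

    def test_row_order_invariance(self):
        X, y = self._planted(n=120)
        res1 = scoring.optimize_weights((X, y), grid_step=0.1, weight_sum_range=(0.9, 1.1))
        perm = np.random.default_rng(5).permutation(len(y))
        res2 = scoring.optimize_weights(
            (X[perm], y[perm]), grid_step=0.1, weight_sum_range=(0.9, 1.1)
        )
        np.testing.assert_array_equal(res1.weights.as_array(), res2.weights.as_array())
        assert res1.f1 == res2.f1

    def test_fixed_threshold_mode(self):
        X, y = self._planted(n=120)
        res = scoring.optimize_weights(
            (X, y), grid_step=0.1, weight_sum_range=(0.9, 1.1), fixed_threshold=0.5
        )
        assert res.threshold == 0.5
        assert 0.0 <= res.f1 <= 1.0


def test_ranking_invariant_under_monotone_cs_rescaling():
    """With fixed weights, any strictly increasing rescale of CS preserves
    the candidate ranking."""
    rng = np.random.default_rng(11)
    w = ScoringWeights()
    cs = []
    for _ in range(20):
        m = rng.uniform(size=4)
        s = scoring.PoseScore(sim2d=m[0], sim3d=m[1], dock_norm=m[2], int_sim_norm=m[3])
        cs.append(scoring.confidence_score(s, w))
    cs = np.array(cs)
    assert (np.argsort(-cs) == np.argsort(-(np.exp(3 * cs) + 7))).all()
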