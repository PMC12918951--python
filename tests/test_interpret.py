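import numpy as np
import pytest
from rdkit import Chem

from tdpred.dmpnn import MPNNConfig, MPNNModel
from tdpred.featurize import Family, FeatureMatrix, FeatureMeta
from tdpred.interpret import (chemical_space_map, mcts_rationale,
                              rank_features, shapley_attributions,
                              target_descriptor_correlation)
from tdpred.model import BoosterConfig, fit
from tdpred.treeshap import TreeEnsemble, shapley_values


def _matrix(values, families=None):
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    families = families or [Family.DESCRIPTOR] * p
    metas = [FeatureMeta(f"c{j}", fam) for j, fam in enumerate(families)]
    return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], metas, values)


from oracles import brute_force_shap as _brute_force_shap


@pytest.fixture(scope="module")
def small_booster():
    rng = np.random.default_rng(3)
    X = rng.random((150, 8))
    y = (X[:, 0] + 0.6 * X[:, 2] + 0.2 * rng.standard_normal(150) > 0.8).astype(int)
    m = _matrix(X)
    fitted = fit(m, y, BoosterConfig(n_trees=15, max_depth=3, learning_rate=0.3, seed=0))
    return fitted, m, y


class TestShapley:
    def test_local_accuracy_on_every_row(self, small_booster):
        fitted, m, _y = small_booster
        attr = shapley_attributions(fitted, m)
        margins = fitted.estimator.predict(m.values, output_margin=True)
        err = np.abs(attr.base_value + attr.values.sum(axis=1) - margins)
        assert err.max() <= 1e-6

    def test_brute_force_oracle_equivalence(self, small_booster):
        fitted, m, _y = small_booster
        ens = TreeEnsemble.from_xgboost(fitted.estimator)
        assert len(ens.used_features()) <= 12
        phi, _base = shapley_values(ens, m.values[:6])
        for r in range(6):
            brute = _brute_force_shap(ens, m.values[r].astype(np.float32), m.values.shape[1])
            assert np.abs(brute - phi[r]).max() < 1e-6

    def test_single_feature_stump(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 1))
        y = (X[:, 0] > 0.5).astype(int)
        fitted = fit(_matrix(X), y, BoosterConfig(n_trees=1, max_depth=1,
                                                  learning_rate=1.0, seed=0))
        attr = shapley_attributions(fitted, _matrix(X))
        margins = fitted.estimator.predict(X, output_margin=True)
        assert np.allclose(attr.values[:, 0], margins - attr.base_value, atol=1e-6)

    def test_unused_feature_has_zero_attribution_and_ranks_last(self, small_booster):
        fitted, m, y = small_booster
        # append a constant column the booster cannot split on
        X2 = np.column_stack([m.values, np.zeros(len(m.ids))])
        m2 = _matrix(X2)
        fitted2 = fit(m2, y, BoosterConfig(n_trees=15, max_depth=3,
                                           learning_rate=0.3, seed=0))
        attr = shapley_attributions(fitted2, m2)
        assert np.abs(attr.values[:, -1]).sum() == 0.0
        ranking = rank_features(attr, top_k=9)
        assert ranking.iloc[-1]["feature"] == "c8"

    def test_rank_features_top_k_exceeding_count(self, small_booster):
        fitted, m, _y = small_booster
        attr = shapley_attributions(fitted, m)
        assert len(rank_features(attr, top_k=100)) == 8

    def test_column_mismatch_rejected(self, small_booster):
        fitted, m, _y = small_booster
        with pytest.raises(ValueError):
            shapley_attributions(fitted, m.select_columns(m.names[:4]))


class TestTargetDescriptorCorrelation:
    def test_identical_columns_r_one_and_symmetry(self):
        rng = np.random.default_rng(0)
        t = (rng.random(100) > 0.5).astype(float)
        m = _matrix(np.column_stack([t, t]), [Family.TARGET, Family.DESCRIPTOR])
        tab = target_descriptor_correlation(m)
        assert tab["pearson_r"].iloc[0] == pytest.approx(1.0)
        m2 = _matrix(np.column_stack([t, t]), [Family.DESCRIPTOR, Family.TARGET])
        tab2 = target_descriptor_correlation(m2)
        assert tab2["pearson_r"].iloc[0] == pytest.approx(tab["pearson_r"].iloc[0])

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(1)
        n = 1000
        targets = (rng.random((n, 5)) > 0.7).astype(float)
        descs = rng.standard_normal((n, 6))
        m = _matrix(np.column_stack([targets, descs]),
                    [Family.TARGET] * 5 + [Family.DESCRIPTOR] * 6)
        tab = target_descriptor_correlation(m)
        assert (np.abs(tab["pearson_r"]) < 0.1).mean() >= 0.95

    def test_constant_column_flagged_zero(self):
        m = _matrix(np.column_stack([np.ones(30), np.arange(30.0)]),
                    [Family.TARGET, Family.DESCRIPTOR])
        tab = target_descriptor_correlation(m)
        assert tab["pearson_r"].iloc[0] == 0.0 and bool(tab["constant"].iloc[0])


class TestMCTS:
    @pytest.fixture(scope="class")
    def encoder(self):
        return MPNNModel(MPNNConfig(depth=2, hidden=16, dropout=0.0, seed=1))

    def test_zero_rollouts_empty(self, encoder):
        assert mcts_rationale(encoder, "c1ccc2ncccc2c1Cl", n_rollouts=0) == []

    def test_too_small_molecule_warns_and_empty(self, encoder):
        with pytest.warns(UserWarning):
            out = mcts_rationale(encoder, "CCO", min_atoms=8)
        assert out == []

    def test_molecule_of_exactly_min_atoms_is_sole_candidate(self, encoder):
        smi = Chem.CanonSmiles("c1ccc2ncccc2c1")  # 10 heavy atoms
        out = mcts_rationale(encoder, smi, min_atoms=10, max_atoms=20,
                             n_rollouts=20, top_k=5)
        assert len(out) == 1
        assert Chem.CanonSmiles(out[0].smiles) == smi

    def test_rationales_are_connected_valid_molecules(self, encoder):
        smi = "COc1ccc2cc3[n+](cc2c1O)CCc1cc2c(cc1-3)OCO2"
        out = mcts_rationale(encoder, smi, min_atoms=8, max_atoms=20,
                             n_rollouts=60, top_k=5)
        assert out
        for rat in out:
            frag = Chem.MolFromSmiles(rat.smiles)
            assert frag is not None
            assert len(Chem.GetMolFrags(frag)) == 1
            assert 8 <= len(rat.atom_indices) <= 20

    def test_deterministic(self, encoder):
        smi = "Cc1ccc2ncccc2c1CCO"
        a = mcts_rationale(encoder, smi, n_rollouts=40, seed=3)
        b = mcts_rationale(encoder, smi, n_rollouts=40, seed=3)
        assert [(r.smiles, r.score) for r in a] == [(r.smiles, r.score) for r in b]


class TestChemicalSpaceMap:
    def test_duplicates_land_together_and_reproducible(self, smiles_corpus):
        from tdpred.fingerprints import compute_ecfp
        fps = np.array([compute_ecfp(s) for s in smiles_corpus[:59]])
        fps = np.vstack([fps, fps[0]])  # duplicate of row 0
        ids = [f"m{i}" for i in range(60)]
        with pytest.warns(UserWarning):  # perplexity auto-reduced for n=60
            tab = chemical_space_map(fps, ids, seed=0)
            tab2 = chemical_space_map(fps, ids, seed=0)
        d_dup = np.hypot(tab.x[59] - tab.x[0], tab.y[59] - tab.y[0])
        others = np.hypot(tab.x[1:59] - tab.x[0], tab.y[1:59] - tab.y[0])
        assert d_dup < np.median(others)
        assert np.allclose(tab[["x", "y"]].values, tab2[["x", "y"]].values)

    def test_two_families_separate(self):
        rng = np.random.default_rng(0)
        a = (rng.random((40, 64)) < 0.1).astype(float)
        a[:, :8] = 1.0
        b = (rng.random((40, 64)) < 0.1).astype(float)
        b[:, -8:] = 1.0
        fps = np.vstack([a, b])
        with pytest.warns(UserWarning):
            tab = chemical_space_map(fps, [f"m{i}" for i in range(80)], seed=1)
        from sklearn.metrics import silhouette_score
        labels = [0] * 40 + [1] * 40
        assert silhouette_score(tab[["x", "y"]].values, labels) > 0.3
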