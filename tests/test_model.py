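import numpy as np
import pytest

from tdpred.dmpnn import MPNNConfig
from tdpred.featurize import Family, FeatureMatrix, FeatureMeta
from tdpred.fingerprints import compute_ecfp
from tdpred.model import (BoosterConfig, PipelineOptions, evaluate, fit,
                          median_config, metrics_from_confusion, nested_cv,
                          sample_booster_config, tune_booster)
from tdpred.split import (add_outer_folds, butina_cluster,
                          cluster_train_test_split)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    metas = [FeatureMeta(f"c{j}", Family.DESCRIPTOR) for j in range(values.shape[1])]
    return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], metas, values)


class TestMetrics:
    def test_printed_confusion_counts_reproduce_precision_and_f1(self):
        """15 predicted active with 13 true positives and 43 false negatives
        give precision 13/15 (0.87) and F1 26/71 (0.37)."""
        m = metrics_from_confusion(tp=13, fp=2, fn=43, tn=400)
        assert m["precision"] == pytest.approx(13 / 15)
        assert m["f1"] == pytest.approx(26 / 71)
        assert round(m["precision"], 2) == 0.87
        assert round(m["f1"], 2) == 0.37

    def test_perfect_classifier(self):
        rep = evaluate([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert rep.mcc == 1.0 and rep.balanced_accuracy == 1.0
        assert rep.roc_auc == 1.0 and rep.f1 == 1.0

    def test_all_negative_predictions_zero_convention(self):
        rep = evaluate([0.1, 0.2, 0.3], [1, 0, 1], threshold=0.5)
        assert rep.precision == 0.0 and rep.f1 == 0.0 and rep.mcc == 0.0
        assert rep.balanced_accuracy == 0.5

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        rep = evaluate(p, y)
        assert rep.tp + rep.fp + rep.fn + rep.tn == 50

    def test_probabilities_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.2], [1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_roc_auc_matches_pairwise_oracle(self):
        """Tie-aware ROC-AUC equals the brute-force pairwise comparison
        P(score_pos > score_neg) + 0.5 P(tie) on n <= 200."""
        rng = np.random.default_rng(7)
        # coarse grid of probabilities forces ties
        p = rng.choice(np.linspace(0, 1, 11), size=200)
        y = (rng.random(200) < 0.3).astype(int)
        rep = evaluate(p, y)
        pos, neg = p[y == 1], p[y == 0]
        wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
        assert rep.roc_auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestBooster:
    def test_separable_toy_perfect_training_auc(self):
        x = np.linspace(0, 1, 40).reshape(-1, 1)
        y = (x.ravel() > 0.5).astype(int)
        m = _matrix(x)
        fitted = fit(m, y, BoosterConfig(n_trees=50, max_depth=2))
        rep = evaluate(fitted.predict_proba(m), y)
        assert rep.roc_auc == 1.0

    def test_constant_labels_error(self):
        m = _matrix(np.random.default_rng(0).random((10, 2)))
        with pytest.raises(ValueError):
            fit(m, [1] * 10, BoosterConfig())

    def test_column_mismatch_at_predict(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.random((20, 3)))
        fitted = fit(m, rng.integers(0, 2, 20), BoosterConfig(n_trees=10))
        other = FeatureMatrix(m.ids, [FeatureMeta("zzz", Family.DESCRIPTOR)] + m.metas[1:],
                              m.values)
        with pytest.raises(ValueError):
            fitted.predict_proba(other)

    def test_tune_argmax_and_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 8))
        y = (X[:, 0] + 0.3 * rng.standard_normal(120) > 0).astype(int)
        m = _matrix(X)
        groups = list(np.arange(120) // 4)
        a = tune_booster(m, y, groups, n_iter=4, inner_k=3, seed=5)
        b = tune_booster(m, y, groups, n_iter=4, inner_k=3, seed=5)
        assert a == b
        single = tune_booster(m, y, groups, n_iter=1, inner_k=3, seed=5)
        assert isinstance(single, BoosterConfig)

    def test_sampled_configs_within_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = sample_booster_config(rng)
            assert 100 <= c.n_trees <= 400
            assert 0.01 <= c.learning_rate <= 0.2
            assert 3 <= c.max_depth <= 10
            assert 0.1 <= c.colsample <= 0.9


class TestMedianConfig:
    def test_identical_configs_returned(self):
        c = BoosterConfig(n_trees=250, learning_rate=0.05, max_depth=4, colsample=0.5)
        assert median_config([c, c, c]) == c

    def test_odd_median(self):
        cs = [BoosterConfig(max_depth=d) for d in (3, 4, 5)]
        assert median_config(cs).max_depth == 4

    def test_even_count_lower_median(self):
        cs = [BoosterConfig(max_depth=d) for d in (3, 4, 5, 6)]
        assert median_config(cs).max_depth == 4


@pytest.fixture(scope="module")
def cv_setup(dataset_400, labels_400):
    records = dataset_400[:240]
    labels = labels_400[:240]
    ids = [r.id for r in records]
    fps = [compute_ecfp(r.smiles_std) for r in records]
    assignment = butina_cluster(fps, 0.4)
    plan = cluster_train_test_split(assignment, labels, ids, seed=4)
    plan = add_outer_folds(plan, assignment, dict(zip(ids, labels.tolist())),
                           ids, k=2, seed=4)
    cluster_of_id = {rid: assignment.cluster_of[i] for i, rid in enumerate(ids)}
    return records, plan, cluster_of_id


class TestNestedCV:
    def test_smoke_run_covers_training_set(self, cv_setup):
        records, plan, cluster_of_id = cv_setup
        opts = PipelineOptions(families=("DESCRIPTOR", "TARGET"), budget=40,
                               n_iter=2, inner_k=2, seed=1)
        reports, configs = nested_cv(records, plan, cluster_of_id, opts)
        assert len(reports) == 2 and len(configs) == 2
        val_ids = [set(r.probabilities) for r in reports]
        assert not (val_ids[0] & val_ids[1])
        assert val_ids[0] | val_ids[1] == set(plan.train_ids)

    def test_gnn_pipeline_learns_planted_signal(self, cv_setup):
        records, plan, cluster_of_id = cv_setup
        opts = PipelineOptions(families=("GNN", "DESCRIPTOR", "TARGET"), budget=80,
                               n_iter=2, inner_k=2, seed=2,
                               mpnn=MPNNConfig(depth=2, hidden=32, ffn_hidden=32,
                                               max_epochs=6))
        reports, _ = nested_cv(records, plan, cluster_of_id, opts)
        assert np.mean([r.roc_auc for r in reports]) > 0.8

    def test_no_test_id_in_folds(self, cv_setup):
        _records, plan, _cluster_of_id = cv_setup
        test = set(plan.test_ids)
        for tr, va in plan.outer_folds:
            assert not (set(tr) | set(va)) & test
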