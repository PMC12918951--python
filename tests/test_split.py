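import numpy as np
import pytest

from tdpred.fingerprints import compute_ecfp
from tdpred.split import (InfeasibleSplitError, add_outer_folds,
                          assert_no_cluster_leakage, butina_cluster,
                          cluster_train_test_split, murcko_scaffold,
                          murcko_scaffold_split, stratified_group_kfold)


from oracles import oracle_butina as _oracle_butina


class TestButina:
    def test_all_distant_gives_singletons(self):
        fps = np.eye(8, dtype=np.uint8)  # pairwise Tanimoto 0
        out = butina_cluster(list(fps), 0.4)
        assert out.n_clusters == 8
        assert all(len(m) == 1 for m in out.members)

    def test_two_identical_plus_one_distant(self):
        fps = [np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])]
        out = butina_cluster(fps, 0.4)
        assert sorted(map(tuple, out.members)) == [(0, 1), (2,)]

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_on_small_sets(self, smiles_corpus, seed):
        """Clustering equals the brute-force sphere-exclusion oracle on
        every fixture of <= 12 molecules."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(smiles_corpus), size=12, replace=False)
        fps = [compute_ecfp(smiles_corpus[i]) for i in idx]
        for cutoff in (0.2, 0.4, 0.65):
            mine = butina_cluster(fps, cutoff).members
            assert mine == _oracle_butina(fps, cutoff)

    def test_empty_input(self):
        out = butina_cluster([], 0.4)
        assert out.n_clusters == 0

    def test_partition_property(self, smiles_corpus):
        fps = [compute_ecfp(s) for s in smiles_corpus[:60]]
        out = butina_cluster(fps, 0.4)
        flat = sorted(i for m in out.members for i in m)
        assert flat == list(range(60))
        assert all(out.cluster_of[i] == c for c, m in enumerate(out.members) for i in m)


class TestClusterTrainTestSplit:
    def test_ten_singletons_fraction(self):
        fps = list(np.eye(10, dtype=np.uint8))
        assignment = butina_cluster(fps, 0.4)
        labels = [0, 1] * 5
        plan = cluster_train_test_split(assignment, labels, [str(i) for i in range(10)],
                                        test_fraction=0.2, seed=0)
        assert len(plan.test_ids) == 2
        assert set(plan.train_ids) | set(plan.test_ids) == {str(i) for i in range(10)}

    def test_cluster_never_straddles(self):
        # one cluster of 5 identical + 5 distant singletons
        same = np.array([1] * 8 + [0] * 8, dtype=np.uint8)
        fps = [same.copy() for _ in range(5)] + list(np.eye(16, dtype=np.uint8)[8:13])
        assignment = butina_cluster(fps, 0.4)
        labels = [1, 0, 0, 0, 0, 1, 0, 0, 0, 0]
        plan = cluster_train_test_split(assignment, labels, [str(i) for i in range(10)],
                                        test_fraction=0.5, seed=3)
        big = set(map(str, range(5)))
        assert big <= set(plan.train_ids) or big <= set(plan.test_ids)

    def test_single_cluster_infeasible(self):
        fps = [np.array([1, 1, 0]) for _ in range(4)]
        assignment = butina_cluster(fps, 0.4)
        with pytest.raises(InfeasibleSplitError):
            cluster_train_test_split(assignment, [0, 1, 0, 1], list("abcd"), seed=0)

    def test_synthetic_split_is_class_balanced(self, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400]
        plan = cluster_train_test_split(assignment, labels_400, ids,
                                        test_fraction=0.2, seed=5)
        lab = dict(zip(ids, labels_400))
        test_frac = np.mean([lab[i] for i in plan.test_ids])
        train_frac = np.mean([lab[i] for i in plan.train_ids])
        global_frac = labels_400.mean()
        assert abs(test_frac - global_frac) <= 0.03
        assert abs(train_frac - global_frac) <= 0.03
        assert abs(len(plan.test_ids) - 0.2 * len(ids)) <= 0.02 * len(ids)

    def test_determinism(self, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400[:100]]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400[:100]]
        a = cluster_train_test_split(assignment, labels_400[:100], ids, seed=9)
        b = cluster_train_test_split(assignment, labels_400[:100], ids, seed=9)
        assert a.to_json() == b.to_json()


class TestStratifiedGroupKFold:
    def test_singleton_groups_balanced(self):
        ids = [f"c{i}" for i in range(10)]
        labels = [0, 1] * 5
        folds = stratified_group_kfold(ids, labels, groups=list(range(10)), k=5, seed=0)
        for _tr, val in folds:
            assert len(val) == 2
            assert sum(labels[ids.index(v)] for v in val) == 1

    def test_group_in_exactly_one_validation_fold(self, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400]
        groups = assignment.cluster_of
        folds = stratified_group_kfold(ids, labels_400, groups, k=5, seed=1)
        seen = []
        for _tr, val in folds:
            seen.extend(val)
            val_groups = {groups[ids.index(v)] for v in val}
            tr_groups = {groups[ids.index(t)] for t in _tr}
            assert not (val_groups & tr_groups)
        assert sorted(seen) == sorted(ids)

    def test_fold_class_ratio_deviation(self, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400]
        lab = dict(zip(ids, labels_400))
        folds = stratified_group_kfold(ids, labels_400, assignment.cluster_of, k=5, seed=1)
        overall = labels_400.mean()
        for _tr, val in folds:
            frac = np.mean([lab[v] for v in val])
            assert abs(frac - overall) <= 0.05

    def test_fewer_groups_than_k(self):
        with pytest.raises(InfeasibleSplitError):
            stratified_group_kfold(["a", "b"], [0, 1], [0, 0], k=3)


class TestMurckoScaffoldSplit:
    def test_single_scaffold_all_in_train_with_warning(self):
        smis = ["c1ccccc1C", "c1ccccc1CC", "c1ccccc1O"]
        with pytest.warns(UserWarning):
            tr, va, te = murcko_scaffold_split(smis, ["a", "b", "c"])
        assert sorted(tr) == ["a", "b", "c"] and not va and not te

    def test_acyclic_molecules_share_empty_bin(self):
        assert murcko_scaffold("CCO") == murcko_scaffold("CCCC") == ""

    def test_partition_sizes_near_quota(self, dataset_400):
        smis = [r.smiles_std for r in dataset_400]
        ids = [r.id for r in dataset_400]
        tr, va, te = murcko_scaffold_split(smis, ids, seed=4)
        n = len(ids)
        assert abs(len(tr) - 0.8 * n) <= 0.05 * n
        assert abs(len(va) - 0.1 * n) <= 0.05 * n
        assert abs(len(te) - 0.1 * n) <= 0.05 * n
        # no scaffold straddles partitions
        part_of = {i: p for p, part in enumerate((tr, va, te)) for i in part}
        scaff = {i: murcko_scaffold(s) for i, s in zip(ids, smis)}
        by_scaffold = {}
        for i in ids:
            by_scaffold.setdefault(scaff[i], set()).add(part_of[i])
        assert all(len(parts) == 1 for parts in by_scaffold.values())


class TestLeakageAudit:
    def test_full_plan_has_zero_leakage(self, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400]
        plan = cluster_train_test_split(assignment, labels_400, ids, seed=2)
        plan = add_outer_folds(plan, assignment, dict(zip(ids, labels_400.tolist())),
                               ids, k=5, seed=2)
        assert_no_cluster_leakage(plan, assignment, ids)

    def test_audit_detects_planted_leak(self, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400]
        plan = cluster_train_test_split(assignment, labels_400, ids, seed=2)
        plan.train_ids.append(plan.test_ids[0])  # plant a leak
        with pytest.raises(AssertionError):
            assert_no_cluster_leakage(plan, assignment, ids)

    def test_plan_json_roundtrip(self, tmp_path, dataset_400, labels_400):
        fps = [compute_ecfp(r.smiles_std) for r in dataset_400[:80]]
        assignment = butina_cluster(fps, 0.4)
        ids = [r.id for r in dataset_400[:80]]
        plan = cluster_train_test_split(assignment, labels_400[:80], ids, seed=2)
        plan.save(tmp_path / "plan.json")
        from tdpred.split import SplitPlan
        back = SplitPlan.load(tmp_path / "plan.json")
        assert back.to_json() == plan.to_json()
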