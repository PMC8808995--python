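"""Stratified splitting, boosted-tree training, evaluation, importance."""

import numpy as np
import pandas as pd
import pytest

from gliaplex.gbm import (
    evaluate_classifier,
    evaluate_scores,
    stratified_split,
    train_gbm,
    variable_importance,
)

SMALL_GRID = {"n_trees": (50, 100), "depth": (1, 2)}


class TestStratifiedSplit:
    def test_exact_20pct_per_stratum(self):
        meta = pd.DataFrame({"diagnosis": ["CTRL"] * 60 + ["AD"] * 40})
        split = stratified_split(meta, seed=0)
        test_dx = meta.loc[split.test_idx, "diagnosis"]
        assert (test_dx == "CTRL").sum() == 12
        assert (test_dx == "AD").sum() == 8

    def test_same_seed_identical_split(self):
        meta = pd.DataFrame({"diagnosis": np.random.default_rng(0).choice(["CTRL", "AD"], 100)})
        a = stratified_split(meta, seed=5)
        b = stratified_split(meta, seed=5)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_and_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        meta = pd.DataFrame({"diagnosis": rng.choice(["CTRL", "AD", "other"], n)})
        split = stratified_split(meta, seed=seed)
        union = np.sort(np.concatenate([split.train_idx, split.test_idx]))
        assert np.array_equal(union, np.arange(n))

    def test_tiny_stratum_goes_to_training(self):
        meta = pd.DataFrame({"diagnosis": ["CTRL"] * 50 + ["AD"] * 3})
        with pytest.warns(UserWarning):
            split = stratified_split(meta, seed=0)
        assert set(np.where(meta["diagnosis"] == "AD")[0]) <= set(split.train_idx)

    def test_group_by_subject_keeps_subjects_together(self):
        rng = np.random.default_rng(1)
        subj = np.repeat([f"s{i}" for i in range(10)], 20)
        meta = pd.DataFrame({"diagnosis": np.where(np.arange(200) < 100, "CTRL", "AD"), "subject": subj})
        split = stratified_split(meta, seed=0, group_by="subject")
        test_subj = set(meta.loc[split.test_idx, "subject"])
        train_subj = set(meta.loc[split.train_idx, "subject"])
        assert not (test_subj & train_subj)


class TestTrainGbm:
    def test_perfectly_separable_feature(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.r_[rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)]])
        y = np.r_[np.zeros(50), np.ones(50)]
        model, cv = train_gbm(X, y, grid=SMALL_GRID, folds=5, seed=0)
        assert cv["cv_accuracy"].max() > 0.97

    def test_grid_search_returns_argmax_of_cv_table(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 3))
        y = (X[:, 0] + 0.5 * rng.standard_normal(120) > 0).astype(int)
        model, cv = train_gbm(X, y, grid=SMALL_GRID, folds=4, seed=1)
        best = cv.loc[cv["cv_accuracy"].idxmax()]
        assert model.n_estimators == int(best["n_trees"])
        assert model.max_depth == int(best["depth"])

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((150, 4))
        y = rng.permutation(np.r_[np.zeros(75), np.ones(75)])
        _, cv = train_gbm(X, y, grid={"n_trees": (50,), "depth": (1,)}, folds=5, seed=2)
        assert cv["cv_accuracy"].max() < 0.65


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        rep = evaluate_scores(y.astype(float), y, n_boot=100, seed=0)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0
        assert rep.p_acc_gt_nir < 1e-6

    def test_separable_toy(self):
        rep = evaluate_scores(np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]), n_boot=50, seed=0)
        assert rep.accuracy == 1.0
        assert 0.4 < rep.threshold < 0.6
        assert rep.auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(1000), np.ones(1000)]
        rep = evaluate_scores(rng.uniform(size=2000), y, n_boot=50, seed=3)
        assert abs(rep.auc - 0.5) < 0.03

    def test_threshold_search_matches_exhaustive(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=60)
        y = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        rep = evaluate_scores(scores, y, n_boot=10, seed=0)
        grid = np.r_[-1.0, np.sort(scores), 2.0]
        best = max(float(((scores >= t).astype(int) == y).mean()) for t in grid)
        assert rep.accuracy == pytest.approx(best)

    def test_cis_bracket_point_estimates(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=200)
        y = (scores > 0.4).astype(int)
        rep = evaluate_scores(scores, y, n_boot=200, seed=5)
        assert rep.accuracy_ci[0] <= rep.accuracy <= rep.accuracy_ci[1]
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]

    def test_multiclass_macro_ovr(self):
        rng = np.random.default_rng(6)
        y = rng.choice(["a", "b", "c"], 150)
        proba = np.full((150, 3), 1 / 3) + rng.normal(0, 0.01, (150, 3))
        proba /= proba.sum(1, keepdims=True)

        class Dummy:
            classes_ = np.array(["a", "b", "c"])

            def predict_proba(self, X):
                return proba

        rep = evaluate_classifier(Dummy(), np.zeros((150, 1)), y, n_boot=50, seed=0)
        assert abs(rep.auc - 0.5) < 0.1
        assert rep.threshold is None


class TestVariableImportance:
    def _fit_planted(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((300, 6))
        y = (X[:, 2] > 0).astype(int)  # only feature 2 is informative
        model, _ = train_gbm(X, y, grid={"n_trees": (100,), "depth": (2,)}, folds=3, seed=seed)
        return model, X, y

    def test_informative_feature_ranked_first_with_100(self):
        model, X, y = self._fit_planted()
        imp = variable_importance(model, X, y, [f"f{i}" for i in range(6)], seed=0)
        assert imp.index[0] == "f2"
        assert imp.iloc[0] == 100.0

    def test_unused_feature_near_zero(self):
        model, X, y = self._fit_planted()
        imp = variable_importance(model, X, y, [f"f{i}" for i in range(6)], seed=0)
        assert imp.drop("f2").max() < 20.0

    def test_ordering_matches_brute_force_single_permutation(self):
        model, X, y = self._fit_planted(seed=1)
        imp = variable_importance(model, X, y, [f"f{i}" for i in range(6)], n_repeats=5, seed=1)
        # independent oracle: leave-one-feature-permuted accuracy drop
        rng = np.random.default_rng(99)
        base = (model.predict(X) == y).mean()
        drops = {}
        for j in range(6):
            vals = []
            for _ in range(5):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(X)), j]
                vals.append(base - (model.predict(Xp) == y).mean())
            drops[f"f{j}"] = np.mean(vals)
        assert max(drops, key=drops.get) == imp.index[0]
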