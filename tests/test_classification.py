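"""Stratified CV, linear SVM, ROC/AUC and the comparison runner."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shgtex import fit_linear_svm, roc_auc, run_comparison, stratified_kfold
from shgtex.classification import ConfigurationError, TextureSVM, UndefinedAUCError
from shgtex.texture import FEATURE_NAMES

from conftest import make_feature_frame
from oracles import concordant_pair_auc


class TestStratifiedKFold:
    def test_perfect_divisibility_one_per_class_per_fold(self):
        labels = [0] * 9 + [1] * 9
        folds = stratified_kfold(labels, k=9, seed=0)
        labels = np.asarray(labels)
        for _, test in folds:
            assert len(test) == 2
            assert labels[test].sum() == 1

    def test_remainders_spread_within_one(self):
        labels = np.array([0] * 10 + [1] * 10)
        folds = stratified_kfold(labels, k=9, seed=1)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(20))
        for _, test in folds:
            assert len(test) in (2, 3)
            for cls in (0, 1):
                n_c = (labels[test] == cls).sum()
                assert abs(n_c - 10 / 9) < 1.0 + 1e-9

    def test_partition_and_disjointness_random_sizes(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(40, 500))
            labels = rng.integers(0, 2, n)
            if min((labels == 0).sum(), (labels == 1).sum()) < 9:
                continue
            folds = stratified_kfold(labels, k=9, seed=3)
            seen = np.concatenate([t for _, t in folds])
            assert sorted(seen) == list(range(n))
            for train, test in folds:
                assert not np.intersect1d(train, test).size

    def test_k_of_one_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_kfold([0, 1] * 5, k=1)

    def test_class_smaller_than_k_named_in_error(self):
        labels = [0] * 20 + [1] * 3
        with pytest.raises(ConfigurationError, match="1"):
            stratified_kfold(labels, k=9)

    def test_grouped_mode_keeps_groups_together(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1] * 3)
        groups = np.repeat(np.arange(8), 3)
        folds = stratified_kfold(labels, k=4, seed=4, groups=groups)
        for train, test in folds:
            assert not set(groups[train]) & set(groups[test])

    def test_deterministic_given_seed(self):
        labels = np.random.default_rng(5).integers(0, 2, 100)
        f1 = stratified_kfold(labels, 9, seed=7)
        f2 = stratified_kfold(labels, 9, seed=7)
        for (a1, b1), (a2, b2) in zip(f1, f2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)


class TestLinearSVM:
    def test_separable_clouds_fit_perfectly(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = fit_linear_svm(X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_svm(np.zeros((5, 2)), np.zeros(5))

    def test_duplicating_training_points_leaves_boundary_unchanged(self):
        """On separable data the max-margin boundary ignores duplication; in
        general the soft-margin objective counts each copy's slack, so the
        duplicated problem at penalty C equals the original at 2C."""
        rng = np.random.default_rng(7)
        Xs = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        ys = np.array([0] * 30 + [1] * 30)
        grid = rng.uniform(-1, 6, (300, 2))
        m1 = fit_linear_svm(Xs, ys)
        m2 = fit_linear_svm(np.vstack([Xs, Xs]), np.concatenate([ys, ys]))
        np.testing.assert_array_equal(m1.predict(grid), m2.predict(grid))

        X = rng.normal(0, 1, (40, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        grid3 = rng.normal(0, 1, (200, 3))
        m3 = fit_linear_svm(X, y, c_param=2.0)
        m4 = fit_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), c_param=1.0)
        np.testing.assert_array_equal(m3.predict(grid3), m4.predict(grid3))

    def test_shuffled_labels_give_chance_level_cv(self):
        """Permutation null: random labels on informative-free features give
        cross-validated accuracy near one half."""
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (400, 6))
        y = np.array([0, 1] * 200)
        accs = []
        for train, test in stratified_kfold(y, 9, seed=8):
            model = TextureSVM().fit(X[train], y[train])
            accs.append((model.predict(X[test]) == y[test]).mean())
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_sklearn_api_surface(self):
        model = TextureSVM(C=2.0)
        assert model.get_params() == {"C": 2.0}
        model.set_params(C=0.5)
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        y = np.array([0, 1] * 10)
        model.fit(X, y)
        assert model.coef_.shape == (1, 4)
        assert model.decision_function(X).shape == (20,)


class TestRocAuc:
    def test_perfect_ordering(self):
        points, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        np.testing.assert_array_equal(points[0], [0, 0])
        np.testing.assert_array_equal(points[-1], [1, 1])

    def test_anti_ordering(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == 0.0

    def test_interleaved_concordance(self):
        """pos {0.9, 0.4}, neg {0.6, 0.1}: 3 of 4 pairs concordant."""
        _, auc = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert auc == 0.75

    def test_matches_concordant_pair_oracle_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            # coarse grid forces plenty of tied scores
            scores = rng.integers(0, 5, n) / 4.0
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(concordant_pair_auc(scores, labels), abs=1e-12)

    def test_monotone_curve(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        points, _ = roc_auc(scores, labels)
        assert (np.diff(points[:, 0]) >= 0).all()
        assert (np.diff(points[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRunComparison:
    def _frame(self, rng, n=30, shift=5.0):
        a = make_feature_frame(rng, n, group="group1", diagnosis="primary_SCC")
        b = make_feature_frame(rng, n, group="group1", diagnosis="metachronous_HGD")
        b["contrast"] += shift
        b["field_id"] = [f"g{i}" for i in range(n)]
        return pd.concat([a, b], ignore_index=True)

    def test_report_invariants(self):
        df = self._frame(np.random.default_rng(12))
        report = run_comparison(df, "group1", k=5, seed=0)
        accs = [f.accuracy for f in report.folds]
        assert report.average_accuracy == pytest.approx(np.mean(accs))
        assert report.best_fold_accuracy == max(accs)
        assert report.folds[report.best_fold_index].accuracy == max(accs)
        for f in report.folds:
            assert f.confusion.sum() == len(f.test_indices)
            trace = f.confusion[0, 0] + f.confusion[1, 1]
            assert f.accuracy == pytest.approx(trace / f.confusion.sum())
        all_test = np.concatenate([f.test_indices for f in report.folds])
        assert sorted(all_test) == list(range(report.n_datapoints))

    def test_determinism(self):
        df = self._frame(np.random.default_rng(13))
        r1 = run_comparison(df, "group1", k=5, seed=3)
        r2 = run_comparison(df, "group1", k=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_no_leakage_from_test_fold_outliers(self):
        """Standardization statistics come from the training fold only: an
        extreme value placed in a fold's test set leaves that fold's scaler
        and model untouched, so its accuracy moves by at most the one
        corrupted sample's own prediction."""
        df = self._frame(np.random.default_rng(14))
        r_base = run_comparison(df, "group1", k=5, seed=5)
        fold = r_base.folds[0]
        victim = int(fold.test_indices[0])
        df_out = df.copy()
        df_out.loc[victim, list(FEATURE_NAMES)] = 1e9
        r_out = run_comparison(df_out, "group1", k=5, seed=5)
        f_out = r_out.folds[0]
        np.testing.assert_array_equal(fold.test_indices, f_out.test_indices)
        assert abs(fold.accuracy - f_out.accuracy) <= 1.0 / len(fold.test_indices) + 1e-12

        # the fitted scaler reflects the (uncorrupted) training rows exactly
        X_out = df_out[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = (df_out["diagnosis"] == "metachronous_HGD").astype(int).to_numpy()
        model = TextureSVM().fit(X_out[fold.train_indices], y[fold.train_indices])
        np.testing.assert_allclose(
            model.pipeline_["scale"].mean_, X_out[fold.train_indices].mean(axis=0)
        )
        assert np.all(model.pipeline_["scale"].mean_ < 1e6)

    def test_grouped_mode_respects_field_boundaries(self):
        rng = np.random.default_rng(15)
        parts = []
        for diag, tag in (("primary_SCC", "a"), ("metachronous_HGD", "b")):
            sub = make_feature_frame(rng, 24, diagnosis=diag)
            sub["field_id"] = [f"{tag}{i // 4}" for i in range(24)]
            parts.append(sub)
        df = pd.concat(parts, ignore_index=True)
        report = run_comparison(df, "group1", k=3, seed=6, grouping="image")
        fields = df["field_id"].to_numpy()
        for f in report.folds:
            assert not set(fields[f.train_indices]) & set(fields[f.test_indices])

    def test_unknown_comparison_and_grouping_rejected(self):
        df = self._frame(np.random.default_rng(16))
        with pytest.raises(ValueError):
            run_comparison(df, "nope")
        with pytest.raises(ValueError):
            run_comparison(df, "group1", grouping="bogus")
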