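"""The bagged-logistic classifier: composition, determinism, CV machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from conftest import model_xy
from mirlog.model import (
    MinorityStratifiedKFold,
    MirlogClassifier,
    cross_validate,
    grid_search,
    load_model,
    rank_auc,
    save_model,
    score_all,
)
from mirlog.simulate import SimConfig, gen_labeled_dataset


class TestRankAuc:
    def test_all_tied_scores_give_half(self):
        assert rank_auc([0, 1, 0, 1], [3.0, 3.0, 3.0, 3.0]) == 0.5

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    def test_matches_brute_force_pair_counting(self, pos, neg):
        """Rank formula equals exhaustive (pos > neg) + 0.5 (pos == neg) counting."""
        y = [1] * len(pos) + [0] * len(neg)
        s = [float(v) for v in pos + neg]
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert rank_auc(y, s) == pytest.approx(oracle, abs=1e-12)
        assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestFit:
    def test_every_learner_trains_on_all_deleterious_rows(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=200, neutral_ratio=4.0, random_state=0).fit(X, y)
        del_rows = set(np.flatnonzero(y == 1))
        n_del = len(del_rows)
        assert len(clf.estimators_) == 200
        for est in clf.estimators_:
            sample = est["sample_idx"]
            assert del_rows <= set(sample)
            assert len(sample) == n_del + round(4.0 * n_del)
            neutral_part = sample[n_del:]
            assert np.all(y[neutral_part] == 0)

    def test_feature_subsets_have_requested_size(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=10, feature_fraction=0.3, random_state=0).fit(X, y)
        k = int(np.ceil(0.3 * clf.n_derived_features_))
        for est in clf.estimators_:
            assert len(est["feature_idx"]) == k
            assert len(set(est["feature_idx"])) == k  # without replacement

    def test_seeded_fit_is_deterministic(self, separable_xy):
        X, y = separable_xy
        a = MirlogClassifier(n_estimators=25, random_state=7).fit(X, y)
        b = MirlogClassifier(n_estimators=25, random_state=7).fit(X, y)
        for ea, eb in zip(a.estimators_, b.estimators_):
            assert np.array_equal(ea["lr"].coef_, eb["lr"].coef_)
            assert np.array_equal(ea["sample_idx"], eb["sample_idx"])

    def test_separable_data_training_auc_is_one(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=50, random_state=0).fit(X, y)
        assert rank_auc(y, clf.predict_score(X)) == 1.0

    def test_single_class_and_bad_params_rejected(self, separable_xy):
        X, y = separable_xy
        with pytest.raises(ValueError, match="both classes"):
            MirlogClassifier().fit(X, np.zeros(len(y), dtype=int))
        for bad in (
            {"l2_strength": -1.0},
            {"neutral_ratio": 0.0},
            {"feature_fraction": 1.5},
            {"n_estimators": 0},
        ):
            with pytest.raises(ValueError):
                MirlogClassifier(**bad).fit(X, y)

    def test_missing_values_rejected(self, separable_xy):
        X, y = separable_xy
        Xm = X.copy()
        Xm[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            MirlogClassifier().fit(Xm, y)


class TestPredict:
    def test_scores_are_probabilities(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=20, random_state=0).fit(X, y)
        s = clf.predict_score(X)
        assert np.all((0 <= s) & (s <= 1))
        assert np.array_equal(clf.predict(X), (s > 0.5).astype(int))

    def test_training_deleterious_rows_score_above_threshold(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=50, random_state=0).fit(X, y)
        assert np.all(clf.predict_score(X[y == 1]) > 0.5)

    def test_identical_learners_equal_single_learner(self, rng):
        # all neutral rows identical -> every bootstrap sample is identical,
        # so the ensemble mean must equal one learner's probability
        X = np.vstack([rng.normal(2, 1, size=(6, 4)), np.tile([0.0, 0.0, 0.0, 1.0], (20, 1))])
        y = np.r_[np.ones(6, dtype=int), np.zeros(20, dtype=int)]
        clf = MirlogClassifier(
            n_estimators=5, feature_fraction=1.0, passthrough_last=False, random_state=0
        ).fit(X, y)
        D = clf._transform(X)
        single = clf.estimators_[0]["lr"].predict_proba(D[:, clf.estimators_[0]["feature_idx"]])[:, 1]
        assert np.allclose(clf.predict_score(X), single, atol=1e-9)

    def test_monotone_in_a_single_deleteriousness_feature(self, rng):
        x = np.r_[rng.normal(2.0, 1, 60), rng.normal(-2.0, 1, 60)]
        y = np.r_[np.ones(60, dtype=int), np.zeros(60, dtype=int)]
        X = np.column_stack([x, np.ones(120)])
        clf = MirlogClassifier(n_estimators=20, feature_fraction=1.0, random_state=0).fit(X, y)
        grid = np.linspace(-4, 4, 81)
        s = clf.predict_score(np.column_stack([grid, np.ones(81)]))
        assert np.all(np.diff(s) > -1e-9)


class TestSplitter:
    def test_minority_rows_dealt_evenly(self):
        y = np.r_[np.ones(24, dtype=int), np.zeros(219, dtype=int)]
        splitter = MinorityStratifiedKFold(n_splits=12, n_repeats=2, random_state=0)
        folds = list(splitter.split(np.zeros((243, 1)), y))
        assert len(folds) == 24
        for repeat in range(2):
            seen = np.zeros(243, dtype=int)
            for train, test in folds[repeat * 12 : (repeat + 1) * 12]:
                assert y[test].sum() == 2  # 24 deleterious / 12 folds
                assert len(test) in (20, 21)
                assert len(np.intersect1d(train, test)) == 0
                seen[test] += 1
            assert np.all(seen == 1)  # partition per repeat

    def test_too_few_minority_rows_advises_fewer_folds(self):
        y = np.r_[np.ones(5, dtype=int), np.zeros(50, dtype=int)]
        with pytest.raises(ValueError, match="fewer folds"):
            list(MinorityStratifiedKFold(n_splits=12).split(np.zeros((55, 1)), y))


class TestCrossValidate:
    def test_every_row_scored_out_of_fold_once_per_repeat(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=10, random_state=0)
        res = cross_validate(clf, X, y, n_splits=12, n_repeats=2, random_state=3)
        assert res.oof_scores.shape == (2, len(y))
        assert not np.isnan(res.oof_scores).any()
        assert res.skipped_folds == []
        assert len(res.per_repeat_auc) == 2
        assert res.mean_auc == pytest.approx(np.mean(res.per_repeat_auc))

    def test_separable_data_cv_auc_high_and_deterministic(self, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=20, random_state=0)
        r1 = cross_validate(clf, X, y, n_splits=12, n_repeats=2, random_state=5)
        r2 = cross_validate(clf, X, y, n_splits=12, n_repeats=2, random_state=5)
        assert r1.per_repeat_auc == r2.per_repeat_auc
        assert r1.mean_auc >= 0.95


class TestGridSearch:
    def test_singleton_grid_returns_that_point(self, separable_xy):
        X, y = separable_xy
        grid = {"l2_strength": [0.5], "neutral_ratio": [2.0], "feature_fraction": [0.6]}
        best, table = grid_search(X, y, grid=grid, n_estimators=10, n_splits=12, n_repeats=1, random_state=0)
        assert best["l2_strength"] == 0.5 and best["neutral_ratio"] == 2.0
        assert len(table) == 1 and "mean_auc" in table.columns

    def test_deterministic_and_tie_break_prefers_regularization(self, separable_xy):
        X, y = separable_xy
        grid = {"l2_strength": [0.1, 1.0], "neutral_ratio": [4.0], "feature_fraction": [1.0]}
        best1, t1 = grid_search(X, y, grid=grid, n_estimators=10, n_splits=12, n_repeats=1, random_state=2)
        best2, t2 = grid_search(X, y, grid=grid, n_estimators=10, n_splits=12, n_repeats=1, random_state=2)
        assert best1 == best2
        assert t1.equals(t2)
        if t1["mean_auc"].nunique() == 1:  # perfect separation ties the grid
            assert best1["l2_strength"] == 1.0


class TestSerialization:
    def test_round_trip_preserves_scores(self, tmp_path, separable_xy):
        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=15, random_state=1).fit(X, y)
        path = tmp_path / "model.json"
        save_model(clf, path)
        loaded = load_model(path)
        assert np.allclose(clf.predict_score(X), loaded.predict_score(X), atol=1e-12)

    def test_score_all_emits_keyed_table(self, separable_xy):
        import pandas as pd

        from mirlog.features import SCORE_COLUMNS

        X, y = separable_xy
        clf = MirlogClassifier(n_estimators=10, random_state=0).fit(X, y)
        frame = pd.DataFrame(X[:, :10], columns=list(SCORE_COLUMNS))
        frame.insert(0, "chrom", "chr1")
        frame.insert(1, "pos", np.arange(len(X)))
        frame.insert(2, "ref", "A")
        frame.insert(3, "alt", "G")
        frame["autosomal"] = X[:, 10].astype(bool)
        out = score_all(clf, frame)
        assert list(out.columns) == ["chrom", "pos", "ref", "alt", "mirlog_score"]
        assert out["mirlog_score"].between(0, 1).all()
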