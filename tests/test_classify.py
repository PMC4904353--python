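"""Age classification: splits, one-vs-one voting, importance, curves, subsampling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from meao.classify import (
    AgeClassifier,
    SvmConfig,
    _OneVsOneSvm,
    _standardize,
    feature_subset_curve,
    pairwise_age_curves,
    rf_importance,
    split_train_test,
    subsample_wells_curve,
    svm_accuracy,
    tune_hyperparameters,
)


class TestSplitTrainTest:
    def _table(self, n=300):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"div": np.tile([5, 7, 9, 12], n // 4),
                             "x": rng.normal(size=n)})

    def test_two_thirds_one_third(self):
        train, test = split_train_test(self._table(300))
        assert (len(train), len(test)) == (200, 100)

    def test_deterministic_given_seed(self):
        t = self._table()
        a1, b1 = split_train_test(t, seed=5)
        a2, b2 = split_train_test(t, seed=5)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_disjoint_partition_covering_all_rows(self):
        t = self._table(88)
        train, test = split_train_test(t, seed=1)
        assert len(train) + len(test) == 88
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(t.index)

    def test_every_class_in_both_parts(self):
        t = self._table(24)
        for seed in range(10):
            train, test = split_train_test(t, seed=seed)
            assert set(train["div"]) == set(test["div"]) == {5, 7, 9, 12}

    def test_single_class_errors(self):
        t = pd.DataFrame({"div": [5] * 30, "x": np.arange(30.0)})
        with pytest.raises(ValueError, match="two classes"):
            split_train_test(t)


class TestOneVsOneSvm:
    def test_six_machines_for_four_classes(self, gaussian_table):
        X = gaussian_table[[f"f{i}" for i in range(4)]].to_numpy()
        y = gaussian_table["div"].to_numpy()
        model = _OneVsOneSvm(SvmConfig()).fit(*_standardize(X, X)[:1], y)
        assert model.n_machines == 6

    def test_matches_sklearn_builtin_ovo_when_votes_decide(self, gaussian_table):
        # independent cross-check: sklearn's SVC is itself one-vs-one
        feats = [f"f{i}" for i in range(4)]
        X = gaussian_table[feats].to_numpy()
        y = gaussian_table["div"].to_numpy()
        Xs, _ = _standardize(X, X)
        ours = _OneVsOneSvm(SvmConfig()).fit(Xs, y).predict(Xs)
        ref = SVC(kernel="rbf", gamma=0.1, C=10.0).fit(Xs, y).predict(Xs)
        assert np.mean(ours == ref) > 0.99

    def test_tie_breaks(self):
        class Stub:
            def __init__(self, answers):
                self.answers = np.asarray(answers)

            def predict(self, X):
                return self.answers

        model = _OneVsOneSvm(SvmConfig())
        model.classes_ = np.array([5, 7, 9, 12])
        # votes: one sample; 5 beats 7, 7 beats 9, 9 beats 5 (cycle) → each of
        # 5,7,9 has 2 votes after the machines against 12 all lose to them
        model.machines = {
            (5, 7): Stub([5]), (5, 9): Stub([9]), (5, 12): Stub([5]),
            (7, 9): Stub([7]), (7, 12): Stub([7]), (9, 12): Stub([9]),
        }
        # three-way tie at 2 votes → lexicographically smallest class
        assert model.predict(np.zeros((1, 2)))[0] == 5
        # two-way tie → the directly contested machine decides
        model.machines[(5, 9)] = Stub([5])  # now 5 has 3 votes, unambiguous
        assert model.predict(np.zeros((1, 2)))[0] == 5
        model.machines = {
            (5, 7): Stub([5]), (5, 9): Stub([5]), (5, 12): Stub([12]),
            (7, 9): Stub([7]), (7, 12): Stub([12]), (9, 12): Stub([9]),
        }
        # votes 5:2, 7:1, 9:1, 12:2 → tie {5, 12}; machine (5, 12) said 12
        assert model.predict(np.zeros((1, 2)))[0] == 12


class TestSvmAccuracy:
    def test_separated_classes_near_perfect(self, gaussian_table):
        res = svm_accuracy(gaussian_table, [f"f{i}" for i in range(4)],
                           n_reps=10, seed=0)
        assert res.mean_accuracy > 99.0
        assert res.confusion.to_numpy().sum() == 10 * 80  # reps × test rows

    def test_memorization_of_repeated_rows(self):
        rows = []
        for div in (5, 7, 9, 12):
            for _ in range(12):
                rows.append({"div": div, "a": float(div), "b": -float(div)})
        res = svm_accuracy(pd.DataFrame(rows), ["a", "b"], n_reps=5, seed=0)
        assert res.mean_accuracy == 100.0

    def test_empty_feature_subset_errors(self, gaussian_table):
        with pytest.raises(ValueError, match="empty"):
            svm_accuracy(gaussian_table, [], n_reps=1)

    def test_reproducible_given_seed(self, gaussian_table):
        feats = [f"f{i}" for i in range(4)]
        r1 = svm_accuracy(gaussian_table, feats, n_reps=5, seed=3)
        r2 = svm_accuracy(gaussian_table, feats, n_reps=5, seed=3)
        np.testing.assert_array_equal(r1.per_repetition, r2.per_repetition)
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)


class TestRandomForest:
    def test_label_leak_feature_ranked_first(self):
        rng = np.random.default_rng(42)
        n = 240
        div = np.tile([5, 7, 9, 12], n // 4)
        df = pd.DataFrame({"div": div, "leak": div.astype(float),
                           **{f"noise{i}": rng.normal(size=n) for i in range(5)}})
        ranking, result = rf_importance(df, n_trees=100, n_reps=5, seed=0)
        assert ranking.index[0] == "leak"
        assert ranking.iloc[0] == pytest.approx(1.0)
        assert ranking.drop("leak").max() < 0.2
        assert result.mean_accuracy == 100.0

    def test_duplicated_signal_columns_still_beat_noise(self):
        rng = np.random.default_rng(1)
        n = 240
        div = np.tile([5, 7, 9, 12], n // 4)
        signal = div + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"div": div, "sig_a": signal, "sig_b": signal,
                           **{f"noise{i}": rng.normal(size=n) for i in range(4)}})
        ranking, _ = rf_importance(df, n_trees=100, n_reps=5, seed=0)
        assert {"sig_a", "sig_b"} == set(ranking.index[:2])

    def test_single_class_errors(self):
        df = pd.DataFrame({"div": [5] * 20, "x": np.arange(20.0)})
        with pytest.raises(ValueError, match="two age classes"):
            rf_importance(df, n_trees=10, n_reps=1)


class TestTuning:
    def test_grid_of_one(self, gaussian_table):
        res = tune_hyperparameters(gaussian_table, gamma_grid=[0.2], cost_grid=[5.0],
                                   k_folds=3, features=[f"f{i}" for i in range(4)])
        assert (res.config.gamma, res.config.cost) == (0.2, 5.0)
        assert res.cv_accuracy.shape == (1, 1)
        assert res.best_accuracy == res.cv_accuracy.iloc[0, 0]

    def test_tie_breaks_toward_smallest_cost_then_gamma(self, gaussian_table):
        # well-separated data: every grid point is perfect → tie rule decides
        res = tune_hyperparameters(gaussian_table, gamma_grid=[0.1, 1.0],
                                   cost_grid=[1.0, 10.0], k_folds=3,
                                   features=[f"f{i}" for i in range(4)])
        assert (res.cv_accuracy.to_numpy() == res.best_accuracy).all()
        assert res.config.cost == 1.0
        assert res.config.gamma == 0.1


@pytest.fixture(scope="module")
def ranked(gaussian_table):
    # only f0..f3 carry signal; add pure-noise features to rank below them
    rng = np.random.default_rng(9)
    df = gaussian_table.copy()
    for i in range(4, 8):
        df[f"f{i}"] = rng.normal(size=len(df))
    ranking, _ = rf_importance(df, n_trees=100, n_reps=3, seed=0)
    return df, ranking


class TestCurves:
    def test_full_subset_equals_all_feature_accuracy(self, ranked):
        df, ranking = ranked
        curve = feature_subset_curve(df, ranking, n_reps=3, seed=1)
        full = svm_accuracy(df, list(ranking.index), n_reps=3, seed=1)
        assert curve.loc[len(ranking), "accuracy"] == pytest.approx(full.mean_accuracy)
        assert ((curve["accuracy"] >= 0) & (curve["accuracy"] <= 100)).all()

    def test_curve_plateaus_once_signal_features_included(self, ranked):
        df, ranking = ranked
        assert set(ranking.index[:4]) == {"f0", "f1", "f2", "f3"}
        curve = feature_subset_curve(df, ranking, n_reps=3, seed=1)
        assert curve.loc[4:, "accuracy"].min() > 95.0

    def test_six_pairwise_curves_for_four_classes(self, ranked):
        df, ranking = ranked
        curves = pairwise_age_curves(df, ranking, n_reps=2, seed=0)
        assert len(curves) == 6
        assert set(curves) == {(5, 7), (5, 9), (5, 12), (7, 9), (7, 12), (9, 12)}
        for curve in curves.values():
            assert curve["accuracy"].iloc[-1] > 95.0  # separated binary problems


class TestSubsampleWells:
    def test_curve_structure_and_reproducibility(self, mini_study_tables):
        well_table, _, _ = mini_study_tables
        c1 = subsample_wells_curve(well_table, n_values=(4, 12), n_trials=8, seed=2)
        c2 = subsample_wells_curve(well_table, n_values=(4, 12), n_trials=8, seed=2)
        pd.testing.assert_frame_equal(c1.table, c2.table)
        t = c1.table
        assert list(t.index) == [4, 12]
        assert ((t["min"] <= t["mean"]) & (t["mean"] <= t["max"])).all()

    def test_full_sampling_uses_every_well(self, mini_study_tables):
        well_table, _, _ = mini_study_tables
        n_wells = well_table.groupby("plate_id")["well_id"].nunique().min()
        curve = subsample_wells_curve(well_table, n_values=(n_wells,), n_trials=3, seed=0)
        assert curve.table.index[0] == n_wells

    def test_oversized_n_errors(self, mini_study_tables):
        well_table, _, _ = mini_study_tables
        with pytest.raises(ValueError, match="n_values"):
            subsample_wells_curve(well_table, n_values=(49,), n_trials=2)
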