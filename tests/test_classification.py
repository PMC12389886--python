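"""Cost-sensitive SVM, T-criterion double CV, RF tuning and metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from painflex import (
    ClassifierSpec,
    CostSensitiveSVM,
    aggregate_subjects,
    confusion_metrics,
    inner_select_csvm,
    make_outer_folds,
    run_outer_cv,
    select_rf,
    sequential_forward_selection,
    t_value,
)
from painflex.classification import CvReport, FoldResult, _mean_inner_t, split_features
from painflex.features import PAIN, PAINLESS


def _toy_table(n_per_trial=20, n_trials=8, effect=3.0, n_features=4, seed=0,
               pain_fraction=0.5):
    """Separable-by-construction feature table grouped by trial."""
    rng = np.random.default_rng(seed)
    rows = []
    for tid in range(n_trials):
        for i in range(n_per_trial):
            pain = i >= n_per_trial * (1 - pain_fraction)
            x = rng.standard_normal(n_features) + (effect if pain else 0.0)
            rows.append([*x, tid, i * 0.125, (i + 2) * 0.125, PAIN if pain else PAINLESS])
    cols = [f"f{k}" for k in range(n_features)] + ["trial_id", "onset_s", "end_s", "label"]
    return pd.DataFrame(rows, columns=cols).astype({"trial_id": int})


class TestTValue:
    @pytest.mark.parametrize(
        "inputs, expected",
        [((1, 1, 1, 1), 1.0), ((0, 0, 0, 0), 0.0), ((0.8, 0.9, 0.7, 0.6), 0.73)],
    )
    def test_weighted_sum(self, inputs, expected):
        assert t_value(*inputs) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            t_value(1.2, 0.5, 0.5, 0.5)


class TestConfusionMetrics:
    def test_direct_arithmetic(self):
        y_true = [PAIN] * 4 + [PAINLESS] * 3
        y_pred = [PAIN] * 3 + [PAINLESS] + [PAIN] + [PAINLESS] * 2
        m = confusion_metrics(y_true, y_pred)
        assert (m.tp, m.tn, m.fp, m.fn) == (3, 2, 1, 1)
        assert m.accuracy == pytest.approx(5 / 7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_perfect_prediction(self):
        y = [PAIN, PAINLESS, PAIN]
        m = confusion_metrics(y, y)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_f1_from_published_subject_rates(self):
        # harmonic mean of the printed precision/recall reproduces the
        # printed F1 (small discrepancy from table rounding)
        pre, rec = 0.8954, 0.9557
        f1 = 2 * pre * rec / (pre + rec)
        assert f1 == pytest.approx(0.9246, abs=2e-4)

    def test_undefined_precision_flagged(self):
        m = confusion_metrics([PAIN, PAINLESS], [PAINLESS, PAINLESS])
        assert math.isnan(m.precision) and m.recall == 0.0 and math.isnan(m.f1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            confusion_metrics([PAIN, "sore"], [PAIN, PAIN])

    def test_identities_on_random_tables(self, rng):
        """Accuracy/precision/recall/F1 satisfy their count definitions."""
        for _ in range(50):
            y_true = rng.choice([PAIN, PAINLESS], size=40)
            y_pred = rng.choice([PAIN, PAINLESS], size=40)
            m = confusion_metrics(y_true, y_pred)
            assert m.tp + m.tn + m.fp + m.fn == 40
            assert m.accuracy == pytest.approx((m.tp + m.tn) / 40)
            if not math.isnan(m.f1):
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12
                )


class TestOuterFolds:
    def test_partition_covers_all_trials(self):
        folds = make_outer_folds(range(8), seed=5)
        assert sorted(t for f in folds for t in f) == list(range(8))
        assert all(len(f) == 2 for f in folds)

    def test_seed_determinism(self):
        assert make_outer_folds(range(8), seed=9) == make_outer_folds(range(8), seed=9)

    def test_indivisible_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_outer_folds(range(7), seed=1)


class TestCostSensitiveSVM:
    def test_separable_toy_perfect_training_accuracy(self):
        df = _toy_table(effect=5.0)
        X, y, _, _ = split_features(df)
        model = CostSensitiveSVM(C=1.0, cost_ratio=1.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_high_positive_cost_forces_minority_recall(self, rng):
        # 1 pain point inside a cloud of 50 painless points
        X = np.vstack([rng.normal(0, 1.0, size=(50, 2)), [[0.5, 0.5]]])
        y = np.array([-1] * 50 + [1])
        cheap = CostSensitiveSVM(C=1.0, cost_ratio=1.0).fit(X, y)
        costly = CostSensitiveSVM(C=1.0, cost_ratio=2.0**10).fit(X, y)
        assert cheap.predict(X[-1:])[0] == -1  # minority point sacrificed
        assert costly.predict(X[-1:])[0] == 1  # high R forces recall = 1

    def test_cost_ratio_symmetry(self, rng):
        """Swapping labels and inverting R mirrors the boundary on a
        symmetric toy set."""
        a = rng.normal(-1.0, 0.8, size=(40, 2))
        b = -a  # point-symmetric classes
        X = np.vstack([a, b])
        y = np.array([-1] * 40 + [1] * 40)
        R = 4.0
        m1 = CostSensitiveSVM(C=1.0, cost_ratio=R).fit(X, y)
        m2 = CostSensitiveSVM(C=R, cost_ratio=1.0 / R).fit(-X, -y)
        # m2 sees the mirrored problem with costs swapped: same hyperplane
        # (up to the solver's stopping tolerance)
        np.testing.assert_allclose(m1.coef_, m2.coef_, rtol=5e-3, atol=1e-5)
        np.testing.assert_allclose(m1.intercept_, -m2.intercept_, rtol=5e-3, atol=1e-5)

    def test_recall_monotone_in_cost_ratio(self, rng):
        """On fixed overlapping data, pain recall never decreases as R grows."""
        X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(1.0, 1, (30, 2))])
        y = np.array([-1] * 60 + [1] * 30)
        recalls = []
        for expo in range(-4, 5):
            model = CostSensitiveSVM(C=1.0, cost_ratio=2.0**expo).fit(X, y)
            pred = model.predict(X)
            recalls.append(np.mean(pred[y == 1] == 1))
        assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            CostSensitiveSVM().fit(np.zeros((5, 2)), np.ones(5))


class TestInnerSelection:
    def test_separable_data_reaches_t_one(self):
        df = _toy_table(effect=6.0)
        sets = [[0, 1], [2, 3], [4, 5]]
        spec = ClassifierSpec(kind="csvm", c_exponents=(0,), r_exponents=(-2, 0, 2))
        R, C, t = inner_select_csvm(df, sets, spec)
        assert t == pytest.approx(1.0)

    def test_singleton_grid_returned(self):
        df = _toy_table()
        spec = ClassifierSpec(kind="csvm", c_exponents=(0,), r_exponents=(0,))
        R, C, _ = inner_select_csvm(df, [[0, 1], [2, 3], [4, 5]], spec)
        assert (R, C) == (1.0, 1.0)

    def test_deterministic(self):
        df = _toy_table(effect=0.5)
        spec = ClassifierSpec(kind="csvm", c_exponents=(-2, 0, 2), r_exponents=(-2, 0, 2))
        sets = [[0, 1], [2, 3], [4, 5]]
        assert inner_select_csvm(df, sets, spec) == inner_select_csvm(df, sets, spec)


class TestRfSelection:
    def test_flat_objective_stays_in_bounds(self):
        df = _toy_table(effect=6.0, n_per_trial=10)
        spec = ClassifierSpec.desk_scale("rf", rf_trees=(10, 50), rf_iterations=6)
        nt, nl, t = select_rf(df, [[0, 1], [2, 3], [4, 5]], spec, seed=3)
        assert 10 <= nt <= 50 and 1 <= nl <= 50

    def test_seed_determinism(self):
        df = _toy_table(effect=1.0, n_per_trial=10)
        spec = ClassifierSpec.desk_scale("rf", rf_trees=(10, 40), rf_iterations=6)
        sets = [[0, 1], [2, 3], [4, 5]]
        assert select_rf(df, sets, spec, seed=11) == select_rf(df, sets, spec, seed=11)

    def test_matches_exhaustive_grid_within_tolerance(self):
        """EI search lands within 0.02 T of a 5x5 exhaustive optimum."""
        from painflex.classification import make_random_forest

        df = _toy_table(effect=1.2, n_per_trial=12, seed=4)
        sets = [[0, 1], [2, 3], [4, 5]]
        spec = ClassifierSpec.desk_scale("rf", rf_trees=(10, 90), rf_min_leaf=(1, 9),
                                         rf_iterations=15)
        best_grid = -1.0
        for nt in (10, 30, 50, 70, 90):
            for nl in (1, 3, 5, 7, 9):
                t, _ = _mean_inner_t(
                    lambda: make_random_forest(nt, nl, 0), df, sets, spec
                )
                best_grid = max(best_grid, t)
        _, _, best_bayes = select_rf(df, sets, spec, seed=0)
        assert best_bayes >= best_grid - 0.02


class TestOuterCv:
    def test_strong_effect_high_accuracy_and_determinism(self):
        df = _toy_table(effect=3.0)
        spec = ClassifierSpec(kind="csvm", c_exponents=(-4, 0, 4), r_exponents=(0,))
        rep1 = run_outer_cv(df, spec, seed=1)
        rep2 = run_outer_cv(df, spec, seed=1)
        assert rep1.mean_metric("accuracy") >= 0.95
        assert [f.params for f in rep1.folds] == [f.params for f in rep2.folds]
        assert [f.metrics for f in rep1.folds] == [f.metrics for f in rep2.folds]

    def test_trial_fold_integrity(self):
        df = _toy_table()
        spec = ClassifierSpec(kind="csvm", c_exponents=(0,), r_exponents=(0,))
        rep = run_outer_cv(df, spec, seed=2)
        seen = [t for f in rep.folds for t in f.test_trials]
        assert sorted(seen) == sorted(df["trial_id"].unique())

    def test_no_leakage_from_test_labels(self):
        """Flipping the held-out labels changes metrics but not the model:
        predictions on the test windows are identical."""
        df = _toy_table(effect=1.0)
        spec = ClassifierSpec(kind="csvm", c_exponents=(0,), r_exponents=(0,))
        rep, models = run_outer_cv(df, spec, seed=3, return_models=True)
        test_trials = rep.folds[0].test_trials
        X_te = df[df["trial_id"].isin(test_trials)]
        flipped = df.copy()
        mask = flipped["trial_id"].isin(test_trials)
        flipped.loc[mask, "label"] = np.where(
            flipped.loc[mask, "label"] == PAIN, PAINLESS, PAIN
        )
        rep_f, models_f = run_outer_cv(flipped, spec, seed=3, return_models=True)
        cols = [f"f{k}" for k in range(4)]
        np.testing.assert_array_equal(
            models[0].predict_labels(X_te[cols].to_numpy()),
            models_f[0].predict_labels(X_te[cols].to_numpy()),
        )


class TestAggregation:
    @staticmethod
    def _report(sid, acc):
        m = confusion_metrics([PAIN, PAINLESS], [PAIN, PAINLESS])
        fold = FoldResult(0, [0, 1], {}, m)
        rep = CvReport("csvm", sid, [fold])
        rep.mean_metric = lambda name, a=acc: a  # fixed metric stub
        return rep

    def test_identical_subjects_zero_std(self):
        reps = [self._report(i, 0.9) for i in range(3)]
        table = aggregate_subjects(reps)
        assert table.loc["mean", "accuracy"] == pytest.approx(0.9)
        assert table.loc["std", "accuracy"] == pytest.approx(0.0)

    def test_mean_and_sample_std(self):
        reps = [self._report(i, a) for i, a in enumerate([0.8, 0.9, 1.0])]
        table = aggregate_subjects(reps)
        assert table.loc["mean", "accuracy"] == pytest.approx(0.9)
        assert table.loc["std", "accuracy"] == pytest.approx(0.1)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            aggregate_subjects([self._report(0, 0.9)])


class TestForwardSelection:
    def test_dominant_feature_selected_first(self, rng):
        rows = []
        for tid in range(6):
            for i in range(16):
                pain = i >= 8
                informative = (4.0 if pain else 0.0) + rng.normal(0, 0.3)
                noise = rng.standard_normal(2)
                rows.append([informative, *noise, tid, 0.0, 0.25,
                             PAIN if pain else PAINLESS])
        df = pd.DataFrame(rows, columns=["sig", "n1", "n2", "trial_id",
                                         "onset_s", "end_s", "label"])
        spec = ClassifierSpec(kind="csvm", c_exponents=(0,), r_exponents=(0,),
                              inner_folds=3)
        trace = sequential_forward_selection(df, spec, seed=0, max_features=2)
        assert trace.iloc[0]["added"] == "sig"
        # the full-set baseline is reported on the same folds
        assert trace.iloc[-1]["added"] == "<full set>"
        assert 0.0 <= trace.iloc[-1]["mean_T"] <= 1.0
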