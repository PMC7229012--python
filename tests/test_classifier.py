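"""Outcome classifiers: balanced accuracy, the lasso-logistic fit and the
cross-validated selection machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskdecode import (
    accuracy_timecourse,
    balanced_accuracy,
    build_classifier_suite,
    cross_classification,
    per_condition_timecourses,
    select_peak_and_lambda,
    train_l1_logistic,
)
from riskdecode.classifier import _cv_balanced_accuracy, wilcoxon_vs_chance
from riskdecode.preprocessing import EpochSet

from oracles import balanced_accuracy_counting, l1_logistic_grid_search


def _epochset(data, outcomes, kind="outcome", **meta_extra):
    n = data.shape[0]
    meta = pd.DataFrame(
        dict(
            trial_id=np.arange(n),
            outcome=outcomes,
            loss_prob_level=meta_extra.get("loss_prob_level", ["low"] * n),
            loss_magnitude=meta_extra.get("loss_magnitude", [0] * n),
            choice=["approach"] * n,
            participant_id=[0] * n,
        )
    )
    return EpochSet(kind=kind, data=data, fs=100.0, bin_width_ms=10.0,
                    window_ms=(0.0, 10.0 * data.shape[2]), meta=meta)


class TestBalancedAccuracy:
    def test_hand_computed_example(self):
        truth = [1] * 4 + [0] * 10
        pred = [1, 1, 1, 0] + [0] * 8 + [1, 1]
        assert balanced_accuracy(pred, truth) == pytest.approx(0.5 * (3 / 4 + 8 / 10))
        assert balanced_accuracy(pred, truth) == pytest.approx(0.775)

    def test_perfect_and_constant_predictions(self):
        truth = [1, 0, 0, 1]
        assert balanced_accuracy(truth, truth) == 1.0
        assert balanced_accuracy([1, 1, 1, 1], truth) == 0.5

    def test_single_class_truth_is_undefined(self):
        with pytest.raises(ValueError):
            balanced_accuracy([1, 0], [1, 1])

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_class_relabelling_symmetry_and_counting_oracle(self, pairs):
        pred = np.array([p for p, _ in pairs])
        truth = np.array([t for _, t in pairs])
        if truth.min() == truth.max():
            return
        score = balanced_accuracy(pred, truth)
        assert score == pytest.approx(balanced_accuracy_counting(pred, truth))
        assert score == pytest.approx(balanced_accuracy(1 - pred, 1 - truth))


class TestL1Logistic:
    def test_objective_matches_brute_force_grid_search(self, rng):
        X = rng.standard_normal((24, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(24) > 0).astype(int)
        for lam in (0.01, 0.1):
            model = train_l1_logistic(X, y, lam)
            ours = model.objective(X, y)
            _, _, oracle = l1_logistic_grid_search(X, y, lam)
            assert ours <= oracle + 1e-4
            assert abs(ours - oracle) < 1e-4

    def test_heavy_penalty_collapses_to_base_rate(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array([0] * 10 + [1] * 30)
        model = train_l1_logistic(X, y, lam=50.0)
        assert np.all(model.weights == 0.0)
        assert model.predict_proba(X) == pytest.approx(np.full(40, 0.75), abs=1e-3)

    def test_weight_sign_follows_separation(self, rng):
        x = np.concatenate([rng.normal(-2, 0.3, 20), rng.normal(2, 0.3, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        model = train_l1_logistic(x, y, lam=0.01)
        assert model.weights[0] > 0

    def test_sparsity_is_monotone_along_the_penalty_path(self, rng):
        X = rng.standard_normal((60, 20))
        beta = np.zeros(20)
        beta[:4] = [2.0, -1.5, 1.0, 0.5]
        y = (X @ beta + rng.standard_normal(60) > 0).astype(int)
        nnz = [
            int(np.sum(train_l1_logistic(X, y, lam).weights != 0))
            for lam in np.logspace(-3, 0, 8)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_rejects_degenerate_input(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            train_l1_logistic(X, np.array([1, 1, 1, 1, 0]), lam=0.1)
        with pytest.raises(ValueError):
            train_l1_logistic(X, np.array([1, 1, 0, 0, 1]), lam=0.0)


class TestAccuracyTimecourse:
    def test_label_independent_features_score_at_chance(self, rng):
        X = rng.standard_normal((120, 30, 3))
        y = np.array(["P"] * 100 + ["N"] * 20)
        curve = accuracy_timecourse(_epochset(X, y), seed=0)
        assert curve.values.shape == (3,)
        assert abs(curve.values.mean() - 0.5) < 0.12

    def test_planted_peak_bin_is_recovered(self, sharp_evoked_session):
        """The evoked response peaks 310 ms post-outcome, i.e. bin 31."""
        curve = accuracy_timecourse(sharp_evoked_session["epochs"]["outcome"], seed=0)
        assert len(curve.values) == 75
        assert abs(curve.peak_bin - 31) <= 2

    def test_fold_reduction_warns_when_class_is_tiny(self, rng):
        X = rng.standard_normal((24, 4, 1))
        y = np.array(["P"] * 20 + ["N"] * 4)
        with pytest.warns(UserWarning, match="folds"):
            accuracy_timecourse(_epochset(X, y), n_folds=5, seed=0)


class TestPeakAndLambdaSelection:
    def test_single_point_grid_returns_it(self, rng):
        X = rng.standard_normal((40, 5, 2))
        y = np.array(["P"] * 25 + ["N"] * 15)
        epochs = _epochset(X, y)
        curve = accuracy_timecourse(epochs, seed=0)
        bin_star, lams = select_peak_and_lambda([curve], [epochs], lambda_grid=[0.025])
        assert lams == [0.025]
        assert bin_star == curve.peak_bin

    def test_identical_curves_reach_consensus_peak(self, rng):
        X = rng.standard_normal((40, 5, 4))
        y = np.array(["P"] * 25 + ["N"] * 15)
        epochs = _epochset(X, y)
        curve = accuracy_timecourse(epochs, seed=0)
        bin_star, _ = select_peak_and_lambda([curve] * 3, [epochs] * 3, lambda_grid=[0.025])
        assert bin_star == curve.peak_bin

    def test_optimised_penalty_dominates_the_default_on_held_out_folds(self, rng):
        # sparse informative pattern: a handful of channels carry the signal
        n, d = 160, 40
        X = rng.standard_normal((n, d, 1))
        beta = np.zeros(d)
        beta[:3] = 1.2
        z = X[:, :, 0] @ beta
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-z)), "P", "N")
        epochs = _epochset(X, y)
        curve = accuracy_timecourse(epochs, seed=0)
        bin_star, lams = select_peak_and_lambda(
            [curve], [epochs], lambda_grid=np.logspace(-4, 0, 10), seed=0
        )
        labels = (epochs.meta["outcome"] == "P").to_numpy().astype(int)
        acc_star = _cv_balanced_accuracy(epochs.at_bin(bin_star), labels, lams[0], 5, 0)
        acc_default = _cv_balanced_accuracy(epochs.at_bin(bin_star), labels, 0.025, 5, 0)
        assert acc_star >= acc_default - 0.05  # within fold noise

    def test_empty_grid_raises(self, rng):
        X = rng.standard_normal((20, 3, 1))
        y = np.array(["P"] * 12 + ["N"] * 8)
        epochs = _epochset(X, y)
        curve = accuracy_timecourse(epochs, seed=0)
        with pytest.raises(ValueError):
            select_peak_and_lambda([curve], [epochs], lambda_grid=[])


class TestClassifierSuite:
    def test_three_contrasts_with_hundred_permuted_each(self, dwell_pipeline):
        suite = dwell_pipeline["suite"]
        for contrast in ("P_vs_N", "P_vs_base", "N_vs_base"):
            assert len(suite[contrast]["permuted"]) == 100
            assert suite[contrast]["model"].label_permutation_id is None
            ids = [m.label_permutation_id for m in suite[contrast]["permuted"]]
            assert ids == list(range(1, 101))

    def test_suite_is_deterministic_given_seed(self, blink_session):
        epochs = blink_session["epochs"]
        a = build_classifier_suite(epochs["outcome"], epochs["baseline"], 31, 0.025,
                                   seed=5, n_permuted=3)
        b = build_classifier_suite(epochs["outcome"], epochs["baseline"], 31, 0.025,
                                   seed=5, n_permuted=3)
        for contrast in ("P_vs_N", "P_vs_base", "N_vs_base"):
            for ma, mb in zip(a[contrast]["permuted"], b[contrast]["permuted"]):
                assert np.array_equal(ma.weights, mb.weights)

    def test_permuted_ensemble_scores_at_chance_on_held_out_data(self, rng):
        n_train, n_test, d = 160, 400, 30
        X = rng.standard_normal((n_train + n_test, d))
        y = (rng.random(n_train + n_test) < 0.3).astype(int)
        accs = []
        rng2 = np.random.default_rng(0)
        for _ in range(60):
            yp = rng2.permutation(y[:n_train])
            model = train_l1_logistic(X[:n_train], yp, 0.025)
            pred = (model.predict_proba(X[n_train:]) > 0.5).astype(int)
            accs.append(balanced_accuracy(pred, y[n_train:]))
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < max(3 * se, 0.02)


class TestCrossClassification:
    def _condition_epochs(self, rng, invariant=True):
        n = 216
        levels = np.repeat(["low", "medium", "high"], n // 3)
        mags = np.tile(np.arange(6), n // 6)
        d = 30
        pattern = np.zeros(d)
        pattern[:5] = 1.0
        y = np.where(rng.random(n) < 0.7, "P", "N")
        X = rng.standard_normal((n, d, 1))
        X[:, :, 0] += np.where(y == "P", 1.0, -1.0)[:, None] * pattern[None, :]
        return _epochset(X, y, loss_prob_level=list(levels), loss_magnitude=list(mags))

    def test_nine_classifiers_per_participant(self, rng):
        epochs = self._condition_epochs(rng)
        acc_p = cross_classification(epochs, "loss_prob", 0, 0.025)
        acc_m = cross_classification(epochs, "loss_mag", 0, 0.025)
        assert len(acc_p) == 3 and len(acc_m) == 6

    def test_condition_invariant_pattern_generalises(self, rng):
        epochs = self._condition_epochs(rng)
        labels = (epochs.meta["outcome"] == "P").to_numpy().astype(int)
        pooled = _cv_balanced_accuracy(epochs.at_bin(0), labels, 0.025, 5, 0)
        accs = cross_classification(epochs, "loss_prob", 0, 0.025)
        for acc in accs.values():
            assert abs(acc - pooled) < 0.12

    def test_wilcoxon_null_calibration_under_shuffled_labels(self):
        """Shuffling labels before the split leaves the group test flat."""
        n_sig = 0
        runs = 50
        for run in range(runs):
            rng = np.random.default_rng(1000 + run)
            accs = []
            for _ in range(6):  # six participants' held-out accuracies
                pred = rng.integers(0, 2, 40)
                truth = np.concatenate([np.ones(20, int), np.zeros(20, int)])
                accs.append(balanced_accuracy(pred, truth))
            res = wilcoxon_vs_chance(np.array(accs))
            n_sig += res.pvalue < 0.05
        assert runs - n_sig >= 0.9 * runs


class TestPerConditionTimecourses:
    def _leveled_epochs(self, rng, amplitudes):
        n_per, d, bins = 60, 20, 40
        pattern = np.zeros(d)
        pattern[:4] = 1.0
        datas, outs, lvls = [], [], []
        for level, amp in amplitudes.items():
            y = np.array(["P"] * 40 + ["N"] * 20)
            X = rng.standard_normal((n_per, d, bins))
            X[:, :, 31] += amp * np.where(y == "P", 1.0, -1.0)[:, None] * pattern[None, :]
            datas.append(X)
            outs.extend(y)
            lvls.extend([level] * n_per)
        return _epochset(np.concatenate(datas), np.array(outs), loss_prob_level=lvls)

    def test_replicated_data_give_identical_curves(self, rng):
        epochs = self._leveled_epochs(rng, {"low": 1.0, "medium": 1.0, "high": 1.0})
        # replace medium/high with exact copies of the low data
        n = 60
        epochs.data[n : 2 * n] = epochs.data[:n]
        epochs.data[2 * n :] = epochs.data[:n]
        epochs.meta.loc[n : 2 * n - 1, "outcome"] = epochs.meta.loc[: n - 1, "outcome"].to_numpy()
        epochs.meta.loc[2 * n :, "outcome"] = epochs.meta.loc[: n - 1, "outcome"].to_numpy()
        out = per_condition_timecourses(epochs, bin_star=31, seed=0)
        assert len(out["curves"]) == 3
        np.testing.assert_allclose(out["curves"]["low"].values, out["curves"]["medium"].values)
        np.testing.assert_allclose(out["curves"]["low"].values, out["curves"]["high"].values)

    def test_baseline_to_peak_orders_with_planted_snr(self, rng):
        epochs = self._leveled_epochs(rng, {"low": 0.2, "medium": 0.6, "high": 1.4})
        out = per_condition_timecourses(epochs, bin_star=31, seed=0)
        b2p = out["baseline_to_peak"]
        assert b2p["low"] < b2p["medium"] < b2p["high"]
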