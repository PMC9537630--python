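"""Logistic/ROC machinery and the SVM split/tune/evaluate protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from pwavekit.errors import ArgumentError, DataError
from pwavekit.risk_models import (evaluate_svm, fit_logistic, make_splits,
                                  roc_auc, run_svm_protocol, train_svm,
                                  tune_svm)


def logistic_cohort(n, beta, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=(n, len(beta)))
    p = 1 / (1 + np.exp(-(x @ np.asarray(beta))))
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))])
    df["poaf"] = y
    return df


class TestFitLogistic:
    def test_null_model_auc_near_half(self):
        df = logistic_cohort(200, [0.0, 0.0], seed=1)
        res = fit_logistic(df, ["x0", "x1"])
        assert abs(res.auc - 0.5) <= 0.08

    def test_perfect_separation_flagged_with_auc_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        df = pd.DataFrame({"x0": x, "poaf": (x > 0).astype(int)})
        res = fit_logistic(df, ["x0"])
        assert res.separation_flag
        assert res.auc == 1.0

    def test_parameter_recovery_within_3_se(self):
        beta = [0.8, -0.5]
        df = logistic_cohort(2000, beta, seed=3)
        res = fit_logistic(df, ["x0", "x1"])
        for name, b in zip(["x0", "x1"], beta):
            lo, hi = res.conf_int.loc[name]
            se = (hi - lo) / (2 * 1.959963984540054)
            assert abs(res.params[name] - b) < 3 * se

    def test_constant_predictor_rejected(self):
        df = logistic_cohort(50, [0.5], seed=4)
        df["c"] = 1.0
        with pytest.raises(ArgumentError, match="c"):
            fit_logistic(df, ["x0", "c"])

    def test_collinear_design_rejected(self):
        df = logistic_cohort(50, [0.5], seed=5)
        df["x_dup"] = 2.0 * df["x0"]
        with pytest.raises(DataError):
            fit_logistic(df, ["x0", "x_dup"])

    def test_noise_predictors_never_reduce_insample_auc(self):
        df = logistic_cohort(150, [0.8, -0.4], seed=6)
        rng = np.random.default_rng(7)
        for i in range(3):
            df[f"noise{i}"] = rng.normal(0, 1, len(df))
        base = fit_logistic(df, ["x0", "x1"]).auc
        for i in range(3):
            cols = ["x0", "x1"] + [f"noise{j}" for j in range(i + 1)]
            assert fit_logistic(df, cols).auc >= base - 1e-12


class TestRocAuc:
    def test_all_ties_give_half(self):
        auc, lo, hi = roc_auc(np.full(20, 0.3), np.r_[np.zeros(10),
                                                      np.ones(10)])
        assert auc == 0.5

    def test_perfect_ranking_gives_one(self):
        auc, lo, hi = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0 and hi == 1.0

    def test_small_worked_example(self):
        auc, _, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ArgumentError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_pairwise_count(self, seed):
        """Mann-Whitney AUC equals the explicit pairwise win count."""
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 25, size=2)
        scores = np.round(rng.random(m + n), 2)  # rounding forces ties
        labels = np.r_[np.ones(m), np.zeros(n)]
        auc, _, _ = roc_auc(scores, labels)
        pos, neg = scores[:m], scores[m:]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (m * n), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestMakeSplits:
    def test_scheme_a_counts_for_study_cohort(self):
        labels = np.r_[np.zeros(66), np.ones(28)]
        sp = make_splits(labels, "A", seed=0)
        assert sp.train_counts == (19, 19)
        assert sp.test_counts == (47, 9)

    def test_scheme_b_balanced_test(self):
        labels = np.r_[np.zeros(66), np.ones(28)]
        sp = make_splits(labels, "B", seed=0)
        assert sp.train_counts == (19, 19)
        assert sp.test_counts == (9, 9)

    def test_scheme_a_partitions_all_patients(self):
        labels = np.r_[np.zeros(66), np.ones(28)]
        sp = make_splits(labels, "A", seed=3)
        union = np.sort(np.concatenate([sp.train_idx, sp.test_idx]))
        assert np.array_equal(union, np.arange(94))

    def test_deterministic_under_seed(self):
        labels = np.r_[np.zeros(20), np.ones(10)]
        a = make_splits(labels, "B", seed=5)
        b = make_splits(labels, "B", seed=5)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_too_small_class_rejected(self):
        with pytest.raises(ArgumentError):
            make_splits(np.r_[np.zeros(50), np.ones(1)], "A", seed=0)


def gaussian_clouds(n_per_class=19, d=7, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(-sep / 2, 1.0, size=(n_per_class, d))
    x1 = rng.normal(+sep / 2, 1.0, size=(n_per_class, d))
    x = np.vstack([x0, x1])
    y = np.r_[np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    return x, y


SMALL_C = [0.1, 1.0, 10.0]
SMALL_G = [0.01, 0.1, 1.0]


class TestSvm:
    def test_separable_clouds_reach_high_cv_accuracy(self):
        x, y = gaussian_clouds(seed=1)
        _, _, cv_acc = tune_svm(x, y, SMALL_C, SMALL_G, k=5, seed=0)
        assert cv_acc >= 0.95

    def test_permuted_labels_near_chance(self):
        x, y = gaussian_clouds(seed=2)
        rng = np.random.default_rng(3)
        _, _, cv_acc = tune_svm(x, rng.permutation(y), SMALL_C, SMALL_G,
                                k=5, seed=0)
        assert abs(cv_acc - 0.5) <= 0.15

    def test_single_grid_cell_returned_verbatim(self):
        x, y = gaussian_clouds(seed=4)
        c, g, _ = tune_svm(x, y, [2.5], [0.07], k=5, seed=0)
        assert (c, g) == (2.5, 0.07)

    def test_k_larger_than_class_rejected(self):
        x, y = gaussian_clouds(n_per_class=4, seed=5)
        with pytest.raises(ArgumentError):
            tune_svm(x, y, SMALL_C, SMALL_G, k=5, seed=0)

    def test_all_correct_predictions_give_unit_metrics(self):
        x, y = gaussian_clouds(seed=6)
        model = train_svm(x, y, 1.0, 0.1)
        m = evaluate_svm(model, x, y)
        assert m["ac"] == m["sen"] == m["spe"] == 1.0

    def test_majority_prediction_arithmetic_on_scheme_a_test(self):
        """Predicting no-POAF for all 47+9 test patients: Ac=47/56."""
        class AllZero:
            def predict(self, x):
                return np.zeros(len(x), dtype=int)
        y = np.r_[np.zeros(47, dtype=int), np.ones(9, dtype=int)]
        m = evaluate_svm(AllZero(), np.zeros((56, 2)), y)
        assert m["ac"] == pytest.approx(47 / 56)
        assert m["sen"] == 0.0 and m["spe"] == 1.0

    def test_metrics_consistent_with_confusion_counts(self):
        x, y = gaussian_clouds(sep=1.0, seed=7)
        model = train_svm(x, y, 1.0, 0.1)
        m = evaluate_svm(model, x, y)
        n = m["tn"] + m["fp"] + m["fn"] + m["tp"]
        assert m["ac"] == pytest.approx((m["tp"] + m["tn"]) / n)
        assert m["sen"] == pytest.approx(m["tp"] / (m["tp"] + m["fn"]))
        assert m["spe"] == pytest.approx(m["tn"] / (m["tn"] + m["fp"]))

    def test_protocol_deterministic_end_to_end(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, size=(94, 7))
        y = np.r_[np.zeros(66, dtype=int), np.ones(28, dtype=int)]
        x[y == 1] += 0.8
        a = run_svm_protocol(x, y, "A", seed=11, c_grid=SMALL_C,
                             gamma_grid=SMALL_G)
        b = run_svm_protocol(x, y, "A", seed=11, c_grid=SMALL_C,
                             gamma_grid=SMALL_G)
        assert a == b
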