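import math
import warnings

import numpy as np
import pandas as pd
import pytest

from cbbct.stats import (
    StepwiseLogisticRegression,
    chi_square_or_fisher,
    compare_groups,
    delong_auc_variance,
    delong_test,
    evaluate_model,
    logistic_multivariable_backward,
    logistic_univariable,
    roc_analysis,
)

# --------------------------------------------------------------------------
# independent oracles (kept deliberately naive and loop-based)


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, labels):
    """Direct structural-component computation of the paired AUC variance."""
    pos_idx = [i for i, l in enumerate(labels) if l]
    neg_idx = [i for i, l in enumerate(labels) if not l]
    m, n = len(pos_idx), len(neg_idx)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    def components(scores):
        v10 = [sum(psi(scores[i], scores[j]) for j in neg_idx) / n for i in pos_idx]
        v01 = [sum(psi(scores[i], scores[j]) for i in pos_idx) / m for j in neg_idx]
        return v10, v01

    v10a, v01a = components(scores_a)
    v10b, v01b = components(scores_b)
    auc_a = sum(v10a) / m
    auc_b = sum(v10b) / m

    def cov(u, v):
        mu, mv = sum(u) / len(u), sum(v) / len(v)
        return sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)

    var = (
        cov(v10a, v10a) / m + cov(v01a, v01a) / n
        + cov(v10b, v10b) / m + cov(v01b, v01b) / n
        - 2 * (cov(v10a, v10b) / m + cov(v01a, v01b) / n)
    )
    return auc_a, auc_b, var


# --------------------------------------------------------------------------
# group comparisons


class TestCompareGroups:
    def test_identical_groups_are_not_separated(self):
        g = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="mannwhitney")
        assert g.p_value == pytest.approx(1.0)

    def test_mann_whitney_u_matches_pair_count(self):
        # U of the first group = number of (x > y) pairs = 0 here
        g = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], test="mannwhitney")
        assert g.statistic == 0.0

    def test_gate_picks_mannwhitney_for_skewed_data(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1.5, 60)
        y = rng.lognormal(0, 1.5, 60)
        assert compare_groups(x, y).test_name == "mann-whitney"

    def test_gate_picks_t_for_normal_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0, 1, 60)
        assert compare_groups(x, y).test_name == "welch-t"

    def test_tiny_group_forces_mannwhitney_with_warning(self):
        with pytest.warns(UserWarning, match="Mann-Whitney"):
            g = compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])
        assert g.test_name == "mann-whitney"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0])

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            if compare_groups(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestContingency:
    def test_perfect_independence(self):
        res = chi_square_or_fisher([[5, 5], [5, 5]])
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        res = chi_square_or_fisher([[10, 0], [0, 10]])
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_receptor_table_bracketed_by_correction_variants(self):
        # the printed p for this 2x2 receptor table lies between the
        # uncorrected and the continuity-corrected chi-square values
        table = [[6, 7], [30, 38]]
        lo = chi_square_or_fisher(table, correction=False).p_value
        hi = chi_square_or_fisher(table, correction=True).p_value
        assert lo <= 0.951 <= hi

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_or_fisher([[0, 0], [3, 4]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_or_fisher([[1.5, 2], [3, 4]])


# --------------------------------------------------------------------------
# ROC / DeLong


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 2.5 <= r.cutoff <= 3.0

    def test_auc_equals_pair_concordance_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(6, 25)
            scores = rng.integers(0, 8, n).astype(float)  # plenty of ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, max(1, n // 3), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            r = roc_analysis(scores, labels, direction="higher")
            assert r.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_auto_orientation_never_below_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = (scores < 0).astype(int)  # anti-predictive
        r = roc_analysis(scores, labels, direction="auto")
        assert r.direction == "lower"
        assert r.auc >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60) + np.repeat([0, 1], 30)
        labels = np.repeat([0, 1], 30)
        r = roc_analysis(scores, labels)
        assert r.auc_ci_95[0] <= r.auc <= r.auc_ci_95[1]


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        assert delong_test(scores, scores, labels) == 1.0

    def test_symmetry_in_score_arguments(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(size=20)
        labels = np.repeat([0, 1], 10)
        assert delong_test(a, b, labels) == pytest.approx(delong_test(b, a, labels))

    def test_variance_matches_independent_oracle_small_fixture(self):
        labels = [1, 1, 1, 0, 0, 0, 0, 1]
        a = [0.9, 0.7, 0.55, 0.2, 0.6, 0.1, 0.3, 0.8]
        b = [0.8, 0.3, 0.6, 0.4, 0.5, 0.2, 0.7, 0.9]
        auc_a, auc_b, var = delong_oracle(a, b, labels)
        av, _ = delong_auc_variance(a, labels)
        bv, _ = delong_auc_variance(b, labels)
        assert av == pytest.approx(auc_a) and bv == pytest.approx(auc_b)
        from scipy.stats import norm

        expected_p = 2 * norm.sf(abs(auc_a - auc_b) / math.sqrt(var))
        assert delong_test(a, b, labels) == pytest.approx(expected_p, rel=1e-12)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections, n_rep = 0, 1000
        for _ in range(n_rep):
            a = rng.normal(size=40)
            b = 0.6 * a + rng.normal(size=40)  # correlated but equally useless
            labels = np.zeros(40, int)
            labels[rng.choice(40, 16, replace=False)] = 1
            if delong_test(a, b, labels) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


# --------------------------------------------------------------------------
# logistic regression


class TestLogisticUnivariable:
    def test_two_by_two_or_is_cross_product_ratio(self):
        a, b, c, d = 20, 10, 15, 30  # exposed/outcome cell counts
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])
        y = np.repeat([1, 0, 1, 0], [a, b, c, d])
        res = logistic_univariable(x, y)
        assert res.table["or_"].iloc[0] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_constant_feature_is_uninformative(self):
        res = logistic_univariable(np.ones(20), np.repeat([0, 1], 10))
        assert res.table["or_"].iloc[0] == 1.0
        assert res.table["p"].iloc[0] == 1.0

    def test_recovers_true_odds_ratio(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.3 + math.log(2) * x)))
        y = rng.random(n) < p
        res = logistic_univariable(x, y.astype(int))
        log_or = math.log(res.table["or_"].iloc[0])
        se = res.table["se"].iloc[0]
        assert abs(log_or - math.log(2)) < 3 * se

    def test_perfect_separation_flagged(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = logistic_univariable(x, y)
        assert res.separation

    def test_ci_contains_or(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(int)
        row = logistic_univariable(x, y).table.iloc[0]
        assert row["ci_low"] <= row["or_"] <= row["ci_high"]


class TestStepwise:
    def _data(self, n=1000, seed=10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"signal": rng.normal(size=n), "noise": rng.normal(size=n)}
        )
        p = 1 / (1 + np.exp(-1.2 * X["signal"]))
        y = (rng.random(n) < p).astype(int)
        return X, y

    def test_noise_predictor_removed(self):
        X, y = self._data()
        res = logistic_multivariable_backward(X, y)
        assert res.retained == ["signal"]
        assert res.steps and res.steps[0][0] == "noise"

    def test_single_candidate_reduces_to_univariable(self):
        X, y = self._data()
        multi = logistic_multivariable_backward(X[["signal"]], y)
        uni = logistic_univariable(X["signal"].to_numpy(), y, name="signal")
        assert multi.table["or_"]["signal"] == pytest.approx(
            uni.table["or_"]["signal"], rel=1e-8
        )

    def test_collinear_duplicate_dropped_with_warning(self):
        X, y = self._data(n=400)
        X["copy"] = X["signal"] * 2.0
        with pytest.warns(UserWarning, match="collinear"):
            res = logistic_multivariable_backward(X[["signal", "copy", "noise"]], y)
        assert "copy" not in res.retained

    def test_alpha_remove_extremes(self):
        X, y = self._data(n=400)
        keep_all = logistic_multivariable_backward(X, y, alpha_remove=1.0)
        assert set(keep_all.retained) == {"signal", "noise"}
        with pytest.warns(UserWarning, match="intercept-only"):
            none = logistic_multivariable_backward(X, y, alpha_remove=0.0)
        assert none.retained == []

    def test_sklearn_estimator_contract(self):
        X, y = self._data(n=300)
        est = StepwiseLogisticRegression(alpha_remove=0.1)
        assert est.get_params() == {"alpha_remove": 0.1}
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (300, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}


class TestEvaluateModel:
    def test_separable_data_reaches_perfect_auc(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        model = StepwiseLogisticRegression(alpha_remove=1.0).fit(X, y)
        roc = evaluate_model(model, X, y)
        assert roc.auc == 1.0
        assert 0.0 <= roc.cutoff <= 1.0  # probability scale

    def test_cutoff_on_probability_scale(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = (rng.random(200) < 1 / (1 + np.exp(-X["x"]))).astype(int)
        model = StepwiseLogisticRegression(alpha_remove=1.0).fit(X, y)
        roc = evaluate_model(model, X, y)
        assert 0.0 <= roc.cutoff <= 1.0
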