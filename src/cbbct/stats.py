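"""Group comparisons, ROC/DeLong analysis, and logistic response modeling.

This module implements the statistical workflow used to relate imaging
features to pathologic complete response:

* continuous two-group comparisons with a Shapiro-Wilk normality gate
  (Welch t-test when both groups look normal, Mann-Whitney U otherwise),
* categorical comparisons by Pearson chi-square or Fisher's exact test,
* empirical ROC analysis with the Youden-index cutoff and DeLong variance
  for the AUC confidence interval and the test against AUC = 0.5,
* DeLong's paired test for correlated AUCs via placement values,
* univariable logistic regression and a backward-stepwise multivariable
  model exposed as an sklearn-style estimator.

Odds ratios are ``exp(coef)`` per unit of the predictor with Wald standard
errors on the log scale, the convention of standard regression tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "GroupComparison",
    "ContingencyResult",
    "RocResult",
    "RegressionResult",
    "compare_groups",
    "chi_square_or_fisher",
    "roc_analysis",
    "delong_auc_variance",
    "delong_test",
    "logistic_univariable",
    "StepwiseLogisticRegression",
    "logistic_multivariable_backward",
    "evaluate_model",
]


# --------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "welch-t" | "mann-whitney"
    statistic: float
    p_value: float
    group_summaries: Dict[str, Dict[str, float]]


def _summaries(x: np.ndarray, y: np.ndarray) -> Dict[str, Dict[str, float]]:
    out = {}
    for name, v in (("group0", x), ("group1", y)):
        out[name] = {
            "n": int(v.size),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)),
            "iqr_low": float(np.percentile(v, 25)),
            "iqr_high": float(np.percentile(v, 75)),
        }
    return out


def _is_normal(v: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(v) == 0:
        return False  # degenerate; Shapiro undefined on constant samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(v).pvalue > alpha


def compare_groups(values, labels=None, *, test: str = "auto") -> GroupComparison:
    """Two-group comparison of a continuous variable.

    Either pass ``(values, labels)`` with binary labels, or two sequences
    ``(group0, group1)``. ``test`` forces ``"t"`` or ``"mannwhitney"``;
    ``"auto"`` applies the Shapiro-Wilk gate at alpha 0.05 per group (groups
    with fewer than 3 observations force Mann-Whitney with a warning).
    """
    second = np.asarray(labels)
    is_label_vector = second.dtype == bool or (
        np.issubdtype(second.dtype, np.integer) and set(np.unique(second)) <= {0, 1}
    )
    if is_label_vector:
        values = np.asarray(values, float)
        lab = second.astype(int)
        if lab.shape != values.shape:
            raise ValueError("labels must align with values")
        x, y = values[lab == 0], values[lab == 1]
    else:  # two groups passed directly
        x, y = np.asarray(values, float), second.astype(float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")

    if test == "auto":
        if min(x.size, y.size) < 3:
            warnings.warn("group with <3 observations: forcing Mann-Whitney U")
            test = "mannwhitney"
        else:
            test = "t" if (_is_normal(x) and _is_normal(y)) else "mannwhitney"

    if test == "t":
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "welch-t"
        if not np.isfinite(stat):  # identical constant groups
            stat, p = 0.0, 1.0
    elif test == "mannwhitney":
        name = "mann-whitney"
        if np.ptp(np.concatenate([x, y])) == 0:
            stat, p = float(x.size * y.size / 2.0), 1.0  # all tied
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(name, stat, p, _summaries(x, y))


@dataclass(frozen=True)
class ContingencyResult:
    p_value: float
    method: str  # "chi-square" | "chi-square-yates" | "fisher"
    statistic: Optional[float] = None


def chi_square_or_fisher(table, correction: bool = False) -> ContingencyResult:
    """Categorical association test on a 2 x k contingency table.

    Fisher's exact test is used for 2 x 2 tables with any expected cell
    count at or below 5, otherwise Pearson chi-square (``correction`` toggles the
    Yates continuity correction on 2 x 2 tables). Larger sparse tables fall
    back to chi-square with a warning, as no exact k-column test is
    available.
    """
    t = np.asarray(table)
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if t.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    expected = sps.contingency.expected_freq(t)
    # inclusive threshold: borderline-sparse tables also get the exact test
    if (expected <= 5).any():
        if t.shape == (2, 2):
            _, p = sps.fisher_exact(t, alternative="two-sided")
            return ContingencyResult(float(p), "fisher")
        warnings.warn(
            "expected counts below 5 in a non-2x2 table; using chi-square anyway"
        )
    chi2, p, _, _ = sps.chi2_contingency(t, correction=correction)
    method = "chi-square-yates" if (correction and t.shape == (2, 2)) else "chi-square"
    return ContingencyResult(float(p), method, float(chi2))


# --------------------------------------------------------------------------
# ROC / DeLong


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_95: Tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    p_value: float  # AUC vs 0.5, DeLong variance
    direction: str = "higher"  # which score direction indicates the positive class
    n_pos: int = 0
    n_neg: int = 0


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: per-positive and per-negative mean
    concordance indicators (ties get half credit)."""
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def _as_binary(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        return lab
    uniq = np.unique(lab)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two classes")
    return lab == uniq[1]


def delong_auc_variance(scores, labels) -> Tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimator)."""
    labels = _as_binary(labels)
    scores = np.asarray(scores, float)
    v10, v01, auc = _placements(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_analysis(scores, labels, direction: str = "auto") -> RocResult:
    """Empirical ROC with Youden-index operating point.

    ``direction="auto"`` orients the score so that AUC >= 0.5 and records the
    chosen orientation; ``"higher"``/``"lower"`` fix it. AUC equals the
    tie-corrected pairwise concordance probability; its CI and the test
    against 0.5 use the DeLong variance.
    """
    labels = _as_binary(labels)
    scores = np.asarray(scores, float)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    auc_raw, _ = delong_auc_variance(scores, labels)
    if direction == "auto":
        direction = "lower" if auc_raw < 0.5 else "higher"
    elif direction not in ("higher", "lower"):
        raise ValueError("direction must be 'auto', 'higher' or 'lower'")
    oriented = -scores if direction == "lower" else scores

    _, var = delong_auc_variance(oriented, labels)
    fpr, tpr, thr = roc_curve(labels, oriented)
    auc = float(_trapezoid_auc(fpr, tpr))  # == tie-corrected pair concordance
    j = tpr - fpr
    idx = int(np.argmax(j))
    cutoff = float(thr[idx])
    if direction == "lower":
        cutoff = -cutoff  # back on the original score scale; positive if score <= cutoff

    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return RocResult(
        auc=float(auc),
        auc_ci_95=ci,
        cutoff=cutoff,
        sensitivity=float(tpr[idx]),
        specificity=float(1.0 - fpr[idx]),
        p_value=p,
        direction=direction,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for two correlated AUCs on the same cases.

    Returns the p-value; degenerate variance (e.g. identical score vectors)
    yields p = 1.
    """
    labels = _as_binary(labels)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors and labels must align")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    v10a, v01a, auc_a = _placements(a, labels)
    v10b, v01b, auc_b = _placements(b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-16:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class RegressionResult:
    """Per-predictor odds ratios with Wald inference, Table-style.

    ``table`` is indexed by predictor name with columns ``or_``, ``ci_low``,
    ``ci_high``, ``se`` (of the log odds ratio) and ``p``. ``params`` holds
    the linear-predictor coefficients including the intercept; ``steps``
    logs backward eliminations as (predictor, p-at-removal).
    """

    table: pd.DataFrame
    params: pd.Series
    retained: List[str]
    steps: List[Tuple[str, float]] = field(default_factory=list)
    separation: bool = False
    llf: float = float("nan")


def _wald_table(fit, names: Sequence[str]) -> pd.DataFrame:
    z = sps.norm.ppf(0.975)
    coef = fit.params[list(names)]
    se = fit.bse[list(names)]
    return pd.DataFrame(
        {
            "or_": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "se": se,
            "p": fit.pvalues[list(names)],
        },
        index=list(names),
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """MLE logistic fit; returns (fit, separation_flag)."""
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=500, method="bfgs")
    separated = bool(np.any(np.abs(fit.params.drop("const", errors="ignore")) > 15))
    return fit, separated


def _validate_outcome(outcome) -> np.ndarray:
    y = np.asarray(outcome).astype(float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must be binary with both classes present")
    return y


def logistic_univariable(feature, outcome, name: str = "x") -> RegressionResult:
    """Single-predictor logistic fit with Wald OR, CI and p.

    A constant feature carries no information: OR 1, p 1. Perfect separation
    is flagged (``separation=True``; the Wald CI is then unbounded in
    spirit and should not be trusted).
    """
    y = _validate_outcome(outcome)
    x = np.asarray(feature, float)
    if np.ptp(x) == 0:
        table = pd.DataFrame(
            {"or_": [1.0], "ci_low": [np.nan], "ci_high": [np.nan], "se": [np.nan], "p": [1.0]},
            index=[name],
        )
        params = pd.Series({"const": logit(y.mean()) if 0 < y.mean() < 1 else 0.0, name: 0.0})
        return RegressionResult(table, params, retained=[name])
    X = pd.DataFrame({name: x})
    fit, separated = _fit_logit(y, X)
    return RegressionResult(
        _wald_table(fit, [name]), fit.params, retained=[name],
        separation=separated, llf=float(fit.llf),
    )


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop later columns that are (numerically) linear combinations of
    earlier ones, warning per dropped column."""
    keep: List[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) < len(keep) + 2:
            warnings.warn(f"dropping collinear predictor {col!r}")
        else:
            keep.append(col)
    return X[keep]


class StepwiseLogisticRegression(BaseEstimator, ClassifierMixin):
    """Backward-stepwise logistic regression (Wald-p elimination).

    Starting from all candidate predictors, the predictor with the largest
    Wald p-value is removed while it exceeds ``alpha_remove``; the surviving
    model is refit at each step. ``alpha_remove=1`` keeps every candidate,
    ``alpha_remove=0`` reduces to the intercept-only model.

    Attributes (after ``fit``): ``result_`` (:class:`RegressionResult`),
    ``retained_``, ``coef_``, ``intercept_``, ``classes_``.
    """

    def __init__(self, alpha_remove: float = 0.05):
        self.alpha_remove = alpha_remove

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        y = _validate_outcome(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        X = _drop_collinear(X.astype(float))
        cols = list(X.columns)
        steps: List[Tuple[str, float]] = []
        fit = separated = None
        while cols:
            fit, separated = _fit_logit(y, X[cols])
            # an unidentifiable (NaN-p) predictor carries no defensible evidence
            pvals = fit.pvalues.drop("const").fillna(1.0)
            worst = str(pvals.idxmax())
            if pvals[worst] <= self.alpha_remove:
                break
            steps.append((worst, float(pvals[worst])))
            cols.remove(worst)
        if not cols:
            warnings.warn("all predictors removed; intercept-only model")
            fit, separated = _fit_logit(y, X[[]])
            table = pd.DataFrame(columns=["or_", "ci_low", "ci_high", "se", "p"])
        else:
            table = _wald_table(fit, cols)
        self.result_ = RegressionResult(
            table, fit.params, retained=list(cols), steps=steps,
            separation=bool(separated), llf=float(fit.llf),
        )
        self.retained_ = list(cols)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.coef_ = fit.params.drop("const").to_numpy()[None, :]
        self.intercept_ = np.asarray([fit.params.get("const", 0.0)])
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float), columns=list(self.feature_names_in_))
        Z = X[self.retained_].to_numpy(float) if self.retained_ else np.zeros((len(X), 0))
        return self.intercept_[0] + Z @ self.coef_[0]

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def logistic_multivariable_backward(
    features: pd.DataFrame, outcome, alpha_remove: float = 0.05
) -> RegressionResult:
    """Backward-stepwise multivariable fit over the given candidates."""
    if features.shape[1] < 1:
        raise ValueError("at least one candidate predictor required")
    model = StepwiseLogisticRegression(alpha_remove=alpha_remove).fit(features, outcome)
    return model.result_


def evaluate_model(model, features, outcome) -> RocResult:
    """Apparent (in-sample style) ROC of a fitted model's probabilities,
    with the Youden cutoff reported on the probability scale."""
    if hasattr(model, "predict_proba"):
        p = np.asarray(model.predict_proba(features))[:, 1]
    else:  # a RegressionResult
        coefs = model.params
        Z = features[model.retained].to_numpy(float) if model.retained else np.zeros(
            (len(features), 0)
        )
        beta = coefs[model.retained].to_numpy() if model.retained else np.zeros(0)
        p = expit(coefs.get("const", 0.0) + Z @ beta)
    return roc_analysis(p, outcome, direction="higher")
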