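"""End-to-end orchestration: simulate -> extract -> analyze -> model.

The cohort table has one row per (patient, timepoint) carrying the kinetic
and morphometric features plus covariates and the response label; reduction
columns are computed against that patient's pre-treatment row. Per-timepoint
analysis mirrors the clinical workflow: group comparisons per parameter,
per-parameter ROC with Youden cutoffs, a pairwise DeLong matrix, and a
baseline categorical table. The predictive model is a univariable screen
(p < 0.05) followed by backward-stepwise logistic regression, evaluated by
its apparent ROC.

Patients missing a timepoint are analyzed per-timepoint with available
cases (complete-case per timepoint), not imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import kinetics, morphometry, stats
from .phantom import (
    AcquisitionSpec,
    CohortParams,
    DynamicExam,
    fat_reference_mask,
    simulate_cohort,
)
from .records import PatientRecord, PatientSeries, TIMEPOINTS

logger = logging.getLogger("cbbct")

#: continuous parameters entering the per-timepoint comparisons / ROC tables
CONTINUOUS_PARAMS = [
    "lesion_density_hu",
    "one_min_enh",
    "two_min_enh",
    "three_min_enh",
    "diameter_mm",
    "calc_volume_mm3",
    "seg_volume_mm3",
    "seg_surface_mm2",
    "washout_rate",
    "max_enh_ratio",
    "wash_in_rate",
]

REDUCTION_PARAMS = ["seg_volume_reduction_pct", "seg_surface_reduction_pct"]

#: candidate predictors for the late-treatment response model
MODEL_CANDIDATES = [
    "one_min_enh",
    "two_min_enh",
    "three_min_enh",
    "wash_in_rate",
    "max_enh_ratio",
    "diameter_mm",
    "seg_volume_mm3",
    "seg_surface_mm2",
    "seg_volume_reduction_pct",
    "seg_surface_reduction_pct",
]


def classify_subtype(er: bool, pr: bool, her2: bool) -> str:
    """Molecular subtype from the three receptor markers: luminal when ER or
    PR is positive; HER2-enriched when both are negative and HER2 positive;
    triple-negative otherwise."""
    if er or pr:
        return "luminal"
    if her2:
        return "her2_enriched"
    return "triple_negative"


def mpg_to_pcr(grade: int) -> bool:
    """Pathologic complete response is Miller-Payne grade 5; grades 1-4
    (including >90% tumor-cell loss) are non-pCR."""
    if grade not in (1, 2, 3, 4, 5):
        raise ValueError(f"Miller-Payne grade must be 1..5, got {grade}")
    return grade == 5


# --------------------------------------------------------------------------
# feature extraction


@dataclass
class ExtractionConfig:
    """Knobs of the measurement stage (defaults match the analysis text)."""

    threshold: Optional[float] = None  # None -> Otsu on the enhancement image
    min_enhancement: float = 10.0  # HU floor to call a lesion resolved
    exclude_necrosis: bool = True
    ellipsoid_method: str = "ellipsoid"


def _measure_exam(exam: DynamicExam, config: ExtractionConfig) -> Dict[str, float]:
    """Per-exam feature dict (kinetics + morphometry, no reductions)."""
    exam = exam.sorted_by_time()
    pre = exam.phase_volumes[0]
    # segment on the strongest-enhancing composite so late low-enhancing
    # lesions are not missed by an unlucky phase choice
    enh_stack = exam.phase_volumes[1:] - pre[None]
    composite = pre + enh_stack.max(axis=0)
    mask = morphometry.segment_lesion(
        composite,
        pre,
        exam.spacing,
        threshold=config.threshold,
        min_enhancement=config.min_enhancement,
    )
    feats: Dict[str, float] = {"seg_empty": float(not mask.any())}
    if not mask.any():
        for k in CONTINUOUS_PARAMS:
            feats[k] = 0.0
        return feats

    morph = morphometry.morphometric_features(mask, exam.spacing)
    fat = fat_reference_mask(exam.shape)
    curve = kinetics.build_curve(exam, mask, fat, exclude_necrosis=config.exclude_necrosis)
    if curve.base_corrected <= 0:
        # ROI indistinguishable from fat: no measurable residual lesion
        logger.info("non-physical ROI at %s: treating lesion as resolved", exam.timepoint_label)
        feats["seg_empty"] = 1.0
        for k in CONTINUOUS_PARAMS:
            feats[k] = 0.0
        return feats
    kin = kinetics.kinetic_features(curve)
    feats.update(
        lesion_density_hu=curve.base_corrected + float(pre[fat].mean()),
        one_min_enh=kin.one_min_enh,
        two_min_enh=kin.two_min_enh,
        three_min_enh=kin.three_min_enh,
        max_enh_ratio=kin.max_enh_ratio,
        wash_in_rate=kin.wash_in_rate,
        washout_rate=kin.washout_rate,
        diameter_mm=morph.diameter_mm,
        calc_volume_mm3=morph.calc_volume_mm3,
        seg_volume_mm3=morph.seg_volume_mm3,
        seg_surface_mm2=morph.seg_surface_mm2,
    )
    return feats


def extract_features(
    series: PatientSeries, config: Optional[ExtractionConfig] = None
) -> pd.DataFrame:
    """One cohort-table row per available timepoint of one patient.

    Reduction columns are relative to the pre-treatment row; without a
    pre-treatment exam they stay missing (flagged by ``baseline_missing``).
    """
    config = config or ExtractionConfig()
    rec = series.record
    rows = []
    baseline: Optional[Dict[str, float]] = None
    for tp in TIMEPOINTS:
        if tp not in series.exams:
            continue
        feats = _measure_exam(series.exams[tp], config)
        if tp == "pre":
            baseline = feats
        row = {
            "patient_id": rec.patient_id,
            "timepoint": tp,
            "age": rec.age,
            "side": rec.side,
            "hormone_status": rec.hormone_status,
            "her2": "positive" if rec.her2 else "negative",
            "ki67_class": rec.ki67_class,
            "subtype": rec.subtype,
            "mpg_grade": rec.mpg_grade,
            "pcr": rec.pcr,
            "baseline_missing": baseline is None,
        }
        row.update(feats)
        if baseline is not None and baseline["seg_volume_mm3"] > 0:
            row["seg_volume_reduction_pct"] = morphometry.reduction(
                baseline["seg_volume_mm3"], feats["seg_volume_mm3"]
            )
            row["seg_surface_reduction_pct"] = morphometry.reduction(
                baseline["seg_surface_mm2"], feats["seg_surface_mm2"]
            )
        else:
            row["seg_volume_reduction_pct"] = np.nan
            row["seg_surface_reduction_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort(
    cohort: Iterable[PatientSeries], config: Optional[ExtractionConfig] = None
) -> pd.DataFrame:
    """Cohort table over all patients (row order is patient order, but every
    row is computed independently, so processing order cannot leak)."""
    frames = [extract_features(s, config) for s in cohort]
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# per-timepoint analysis


def _params_for(timepoint: str, columns) -> List[str]:
    params = list(CONTINUOUS_PARAMS)
    if timepoint != "pre":
        params += [p for p in REDUCTION_PARAMS if p in columns]
    return [p for p in params if p in columns]


def run_timepoint_analysis(
    cohort: pd.DataFrame,
    timepoint: str,
    alpha: float = 0.05,
    adjust: str = "none",
) -> Dict[str, pd.DataFrame]:
    """Parameter-wise comparison + ROC tables at one timepoint.

    Returns ``comparisons`` (test, p, group summaries), ``roc`` (AUC, CI,
    Youden cutoff, sensitivity, specificity), ``delong`` (pairwise AUC
    p-values on shared complete cases) and ``categorical`` (baseline
    covariates vs response). ``adjust="holm"`` adds Holm-adjusted p-values
    to the comparisons table.
    """
    sub = cohort[cohort["timepoint"] == timepoint]
    y = sub["pcr"].astype(bool).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError(f"need at least two patients per response class at {timepoint!r}")

    params = _params_for(timepoint, sub.columns)
    comp_rows, roc_rows = [], []
    for p in params:
        v = sub[p].to_numpy(float)
        ok = np.isfinite(v)
        gc = stats.compare_groups(v[ok & ~y], v[ok & y])
        logger.info("compare %s@%s: %s p=%.4g", p, timepoint, gc.test_name, gc.p_value)
        comp_rows.append(
            {
                "parameter": p,
                "test": gc.test_name,
                "statistic": gc.statistic,
                "p": gc.p_value,
                "non_pcr_mean": gc.group_summaries["group0"]["mean"],
                "non_pcr_sd": gc.group_summaries["group0"]["sd"],
                "pcr_mean": gc.group_summaries["group1"]["mean"],
                "pcr_sd": gc.group_summaries["group1"]["sd"],
                "pooled_mean": float(np.nanmean(v)),
                "pooled_sd": float(np.nanstd(v, ddof=1)),
            }
        )
        roc = stats.roc_analysis(v[ok], y[ok], direction="auto")
        roc_rows.append(
            {
                "parameter": p,
                "auc": roc.auc,
                "ci_low": roc.auc_ci_95[0],
                "ci_high": roc.auc_ci_95[1],
                "cutoff": roc.cutoff,
                "direction": roc.direction,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "p": roc.p_value,
            }
        )
    comparisons = pd.DataFrame(comp_rows).set_index("parameter")
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        comparisons["p_holm"] = multipletests(comparisons["p"], method="holm")[1]

    delong = pd.DataFrame(np.ones((len(params), len(params))), index=params, columns=params)
    for i, a in enumerate(params):
        for j, b in enumerate(params):
            if j <= i:
                continue
            va, vb = sub[a].to_numpy(float), sub[b].to_numpy(float)
            ok = np.isfinite(va) & np.isfinite(vb)
            sa = va if stats.roc_analysis(va[ok], y[ok]).direction == "higher" else -va
            sb = vb if stats.roc_analysis(vb[ok], y[ok]).direction == "higher" else -vb
            pval = stats.delong_test(sa[ok], sb[ok], y[ok])
            delong.loc[a, b] = delong.loc[b, a] = pval

    cat_rows = []
    for col in ("side", "hormone_status", "her2", "ki67_class", "subtype"):
        if col not in sub.columns:
            continue
        table = pd.crosstab(sub[col], y).to_numpy()
        if table.shape[1] < 2 or table.shape[0] < 2:
            continue
        res = stats.chi_square_or_fisher(table.T)
        cat_rows.append({"variable": col, "method": res.method, "p": res.p_value})
    categorical = pd.DataFrame(cat_rows)

    return {
        "comparisons": comparisons,
        "roc": pd.DataFrame(roc_rows).set_index("parameter"),
        "delong": delong,
        "categorical": categorical,
    }


# --------------------------------------------------------------------------
# predictive model


@dataclass
class PredictiveModel:
    result: stats.RegressionResult
    roc: stats.RocResult
    screen: pd.DataFrame  # univariable screen table
    timepoint: str
    standardize: bool
    scale_: Dict[str, Dict[str, float]]

    def to_json(self) -> str:
        payload = {
            "timepoint": self.timepoint,
            "retained": self.result.retained,
            "coefficients": {k: float(v) for k, v in self.result.params.items()},
            "odds_ratios": {
                k: float(v) for k, v in self.result.table["or_"].items()
            },
            "steps": [[n, float(p)] for n, p in self.result.steps],
            "standardize": self.standardize,
            "scale": self.scale_,
            "roc": {
                "auc": self.roc.auc,
                "ci": list(self.roc.auc_ci_95),
                "cutoff": self.roc.cutoff,
                "sensitivity": self.roc.sensitivity,
                "specificity": self.roc.specificity,
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def build_predictive_model(
    cohort: pd.DataFrame,
    timepoint: str = "late",
    candidates: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    alpha_remove: float = 0.05,
    standardize: bool = True,
) -> PredictiveModel:
    """Univariable screen then backward-stepwise logistic response model.

    Candidates default to the kinetic/size parameters available at the
    timepoint; only univariably significant candidates (Wald p < ``alpha``)
    enter the multivariable stage. With ``standardize`` the odds ratios are
    per standard deviation of each predictor. Rows with missing candidate
    values are dropped (complete case).
    """
    sub = cohort[cohort["timepoint"] == timepoint]
    cands = [c for c in (candidates or MODEL_CANDIDATES) if c in sub.columns]
    X = sub[cands].astype(float)
    keep = X.notna().all(axis=1)
    X, y = X[keep], sub.loc[keep, "pcr"].astype(int).to_numpy()

    scale: Dict[str, Dict[str, float]] = {}
    if standardize:
        for c in cands:
            mu, sd = float(X[c].mean()), float(X[c].std(ddof=1))
            scale[c] = {"mean": mu, "sd": sd if sd > 0 else 1.0}
            X[c] = (X[c] - mu) / scale[c]["sd"]

    screen_rows = []
    for c in cands:
        uni = stats.logistic_univariable(X[c].to_numpy(), y, name=c)
        row = uni.table.loc[c].to_dict()
        row["parameter"] = c
        screen_rows.append(row)
        logger.info("screen %s@%s: OR=%.3f p=%.4g", c, timepoint, row["or_"], row["p"])
    screen = pd.DataFrame(screen_rows).set_index("parameter")

    selected = [c for c in cands if screen.loc[c, "p"] < alpha]
    if not selected:
        import warnings

        warnings.warn("no univariably significant predictor; intercept-only model")
        result = stats.RegressionResult(
            table=pd.DataFrame(columns=["or_", "ci_low", "ci_high", "se", "p"]),
            params=pd.Series({"const": float(np.log(y.mean() / (1 - y.mean())))}),
            retained=[],
        )
        roc = stats.roc_analysis(
            np.full(len(y), y.mean()) + np.linspace(0, 1e-9, len(y)), y
        )
    else:
        result = stats.logistic_multivariable_backward(
            X[selected], y, alpha_remove=alpha_remove
        )
        logger.info("stepwise@%s retained %s", timepoint, result.retained)
        roc = stats.evaluate_model(result, X, y)
    return PredictiveModel(result, roc, screen, timepoint, standardize, scale)


# --------------------------------------------------------------------------
# end-to-end


def run_all(
    params: Optional[CohortParams] = None,
    acq: Optional[AcquisitionSpec] = None,
    seed: int = 0,
    out_dir=None,
    config: Optional[ExtractionConfig] = None,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> Dict[str, object]:
    """simulate -> extract -> analyze -> model; optionally write outputs.

    Returns the cohort table, per-timepoint analyses and the late-treatment
    model. With ``out_dir`` the tables are written as CSV and the model as
    JSON; a run log records every statistical choice.
    """
    from pathlib import Path

    params = params or CohortParams()
    acq = acq or AcquisitionSpec()
    handler = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        cohort_series = simulate_cohort(params, acq, seed=seed)
        table = extract_cohort(cohort_series, config)
        analyses = {}
        for tp in timepoints:
            try:
                analyses[tp] = run_timepoint_analysis(table, tp)
            except ValueError as e:  # a class absent at this timepoint
                logger.warning("skipping %s: %s", tp, e)
        model = build_predictive_model(table, timepoint="late")
        if out_dir is not None:
            table.to_csv(out / "cohort_features.csv", index=False)
            for tp, tables in analyses.items():
                for name, df in tables.items():
                    df.to_csv(out / f"{tp}_{name}.csv")
            model.screen.to_csv(out / "late_univariable_screen.csv")
            model.result.table.to_csv(out / "late_model_table.csv")
            (out / "late_model.json").write_text(model.to_json())
        return {"cohort": table, "analyses": analyses, "model": model}
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
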