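"""Digital dynamic contrast breast-CT phantom.

Generates four-phase (pre-contrast, 60 s, 120 s, 180 s) attenuation volumes
containing a single ellipsoidal enhancing lesion over a fat background, plus
longitudinal cohorts with response-dependent shrinkage and enhancement
decline, so that the downstream kinetic, morphometric and statistical stages
can be exercised without any patient data.

Attenuation model
-----------------
The lesion's fat-corrected attenuation is ``base = baseline_hu - fat_hu``.
At a post-contrast phase the lesion attenuates at

    ``fat_hu + base * (1 + (peak_ratio - 1) * frac(t))``

where ``frac(t)`` is the fraction of peak enhancement attained at phase time
``t``: 1 at ``t_peak``, falling to ``1 - washout_frac`` at the final phase,
and rising either linearly from 0 (default) or along explicit per-phase
uptake fractions (``enh_fracs``), which lets the generator realise concave
early-uptake curves. Voxel noise is additive i.i.d. Gaussian.

The cohort generator has two consumers with very different budgets, so each
patient can be realised either as rendered voxel volumes
(:func:`simulate_patient`, :func:`simulate_cohort`) or as the analytically
known per-timepoint feature values (:func:`simulate_cohort_table`); both draw
from the identical per-patient sampling routine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import PatientRecord, PatientSeries, TIMEPOINTS

__all__ = [
    "AcquisitionSpec",
    "LesionSpec",
    "GroupLongitudinal",
    "CohortParams",
    "DynamicExam",
    "ellipsoid_mask",
    "fat_reference_mask",
    "render_exam",
    "sample_lesion",
    "simulate_patient",
    "simulate_cohort",
    "true_features",
    "simulate_cohort_table",
    "pattern_params",
]


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and background tissue model.

    ``voxel_size`` is isotropic (mm); ``phase_times`` are seconds from
    injection with the pre-contrast sweep at 0 s. ``fat_hu`` is the adipose
    background (canonically about -100 HU); glandular texture is optional
    (``n_gland_blobs`` unenhancing blobs at ``gland_hu``).
    """

    voxel_size: float = 1.0
    grid_shape: Tuple[int, int, int] = (128, 128, 128)
    phase_times: Tuple[float, ...] = (0.0, 60.0, 120.0, 180.0)
    noise_sd: float = 5.0
    fat_hu: float = -100.0
    gland_hu: float = 0.0
    n_gland_blobs: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.grid_shape) != 3 or any(int(s) < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be three axes of at least 4 voxels")
        times = np.asarray(self.phase_times, float)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("phase_times must strictly increase starting at 0")
        if len(times) < 2:
            raise ValueError("need a pre-contrast and at least one post-contrast phase")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return (self.voxel_size,) * 3

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.voxel_size


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth lesion: geometry plus a four-phase enhancement course.

    ``axes`` are the three principal diameters in mm aligned with the volume
    axes (slice, row, column); ``center`` is in mm (grid center when None).
    ``peak_ratio`` is the true maximum-enhancement ratio -- peak fat-corrected
    attenuation over the pre-contrast fat-corrected attenuation.
    ``enh_fracs``, when given, lists the fraction of peak enhancement at each
    post-contrast phase (must be 1 at ``t_peak`` and ``1 - washout_frac`` at
    the last phase); when None the rise to ``t_peak`` is linear in time.
    """

    axes: Tuple[float, float, float]
    baseline_hu: float
    peak_ratio: float
    t_peak: float = 180.0
    washout_frac: float = 0.0
    center: Optional[Tuple[float, float, float]] = None
    enh_fracs: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.axes) or len(self.axes) != 3:
            raise ValueError("axes must be three positive diameters (mm)")
        if self.peak_ratio < 1:
            raise ValueError("peak_ratio must be >= 1")
        if not (0 <= self.washout_frac < 1):
            raise ValueError("washout_frac must be in [0, 1)")
        if not np.isfinite(self.baseline_hu):
            raise ValueError("baseline_hu must be finite")

    def enhancement_fractions(self, phase_times: Sequence[float]) -> np.ndarray:
        """Fraction of peak enhancement at each post-contrast phase."""
        post = np.asarray(phase_times, float)[1:]
        if self.t_peak not in post:
            raise ValueError(f"t_peak={self.t_peak} is not a sampled post-contrast phase")
        if self.enh_fracs is not None:
            frac = np.asarray(self.enh_fracs, float)
            if frac.shape != post.shape:
                raise ValueError("enh_fracs must give one fraction per post-contrast phase")
            i_peak = int(np.where(post == self.t_peak)[0][0])
            if not math.isclose(frac[i_peak], 1.0):
                raise ValueError("enh_fracs must equal 1 at t_peak")
            if self.t_peak < post[-1] and not math.isclose(
                frac[-1], 1.0 - self.washout_frac, abs_tol=1e-9
            ):
                raise ValueError("enh_fracs[-1] must equal 1 - washout_frac")
            if np.any(frac < 0) or np.any(frac > 1):
                raise ValueError("enh_fracs must lie in [0, 1]")
            return frac
        frac = np.where(post <= self.t_peak, post / self.t_peak, 0.0)
        after = post > self.t_peak
        if after.any():
            span = post[-1] - self.t_peak
            frac[after] = 1.0 - self.washout_frac * (post[after] - self.t_peak) / span
        return frac

    def delta_hu_true(self, phase_times: Sequence[float], fat_hu: float) -> np.ndarray:
        """Noise-free fat-corrected enhancement at each post-contrast phase."""
        base = self.baseline_hu - fat_hu
        return base * (self.peak_ratio - 1.0) * self.enhancement_fractions(phase_times)


@dataclass(frozen=True)
class GroupLongitudinal:
    """Response-group longitudinal change: per-axis linear shrinkage factor
    and enhancement-decline factor (on ``peak_ratio - 1``) at mid and late
    treatment, each as a (mean, sd) normal summary."""

    shrink_mid: Tuple[float, float]
    shrink_late: Tuple[float, float]
    enh_mid: Tuple[float, float]
    enh_late: Tuple[float, float]


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level sampling distributions.

    Pre-treatment marginals default to the pooled pre-treatment population:
    lesion density 204.7 +/- 42.4 HU, largest in-plane diameter
    41.3 +/- 19.1 mm, maximum enhancement ratio 1.42 +/- 0.202, peak mostly at
    the 180 s phase so the wash-in marginal centers near 0.24 %/s, and a 60 s
    uptake fraction drawn so the one-minute enhancement marginal centers at
    75.8 HU. Group separations during treatment are free parameters (the
    source tables publish pooled summaries only).
    """

    n_patients: int = 81
    pcr_prevalence: float = 0.444
    baseline_hu: Tuple[float, float] = (204.7, 42.4)
    baseline_hu_bounds: Tuple[float, float] = (80.0, 400.0)
    diameter: Tuple[float, float] = (41.3, 19.1)
    diameter_bounds: Tuple[float, float] = (6.0, 110.0)
    axis_ratio_range: Tuple[float, float] = (0.55, 0.95)
    peak_ratio: Tuple[float, float] = (1.42, 0.202)
    peak_ratio_bounds: Tuple[float, float] = (1.05, 2.2)
    t_peak_choices: Tuple[float, ...] = (120.0, 180.0)
    t_peak_probs: Tuple[float, ...] = (0.05, 0.95)
    frac60: Tuple[float, float] = (0.572, 0.15)
    frac60_bounds: Tuple[float, float] = (0.05, 1.0)
    frac120: Tuple[float, float] = (0.82, 0.10)
    washout_frac_range: Tuple[float, float] = (0.05, 0.35)
    pcr_group: GroupLongitudinal = field(
        default_factory=lambda: GroupLongitudinal(
            shrink_mid=(0.62, 0.10),
            shrink_late=(0.40, 0.12),
            enh_mid=(0.50, 0.15),
            enh_late=(0.15, 0.10),
        )
    )
    non_pcr_group: GroupLongitudinal = field(
        default_factory=lambda: GroupLongitudinal(
            shrink_mid=(0.85, 0.08),
            shrink_late=(0.75, 0.10),
            enh_mid=(0.85, 0.12),
            enh_late=(0.70, 0.15),
        )
    )
    age_pcr: Tuple[float, float] = (43.4, 8.5)
    age_non_pcr: Tuple[float, float] = (44.0, 10.0)
    age_bounds: Tuple[float, float] = (26.0, 67.0)
    p_right: float = 0.58
    p_hormone_positive: float = 0.42
    p_her2_positive: float = 0.84
    p_ki67_high: float = 0.94
    non_pcr_grade_probs: Tuple[float, ...] = (0.10, 0.25, 0.40, 0.25)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pcr_prevalence <= 1.0):
            raise ValueError("pcr_prevalence must be in [0, 1]")
        for attr in ("shrink_mid", "shrink_late"):
            if getattr(self.pcr_group, attr)[0] > getattr(self.non_pcr_group, attr)[0]:
                raise ValueError(
                    "responders must shrink at least as much as non-responders "
                    f"on average ({attr})"
                )
        if not math.isclose(sum(self.t_peak_probs), 1.0, abs_tol=1e-9):
            raise ValueError("t_peak_probs must sum to 1")


def pattern_params(**overrides) -> CohortParams:
    """Cohort configuration for the qualitative response-pattern study:
    identical pre-treatment groups, separated mid/late groups, and the peak
    pinned at the final phase so the washout rate is uninformative (zero in
    both groups) by construction."""
    base = dict(t_peak_choices=(180.0,), t_peak_probs=(1.0,))
    base.update(overrides)
    return CohortParams(**base)


# --------------------------------------------------------------------------
# exam container and rendering


@dataclass
class DynamicExam:
    """One timepoint's stack of phase volumes (HU) with spacing metadata."""

    phase_volumes: np.ndarray  # (n_phases, nz, ny, nx), HU
    spacing: Tuple[float, float, float]  # mm
    phase_times: Tuple[float, ...]  # s
    timepoint_label: str = "pre"
    lesion: Optional[LesionSpec] = None  # ground truth, when simulated

    def __post_init__(self) -> None:
        self.phase_volumes = np.asarray(self.phase_volumes)
        if self.phase_volumes.ndim != 4:
            raise ValueError("phase_volumes must be (n_phases, nz, ny, nx)")
        if self.phase_volumes.shape[0] != len(self.phase_times):
            raise ValueError("one volume per phase time required")
        if self.timepoint_label not in TIMEPOINTS:
            raise ValueError(f"timepoint_label must be one of {TIMEPOINTS}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.phase_volumes.shape[1:]

    def sorted_by_time(self) -> "DynamicExam":
        order = np.argsort(self.phase_times)
        return DynamicExam(
            self.phase_volumes[order],
            self.spacing,
            tuple(np.asarray(self.phase_times)[order]),
            self.timepoint_label,
            self.lesion,
        )


def _center_coords(shape, spacing):
    """Voxel-center coordinates (mm) per axis."""
    return [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]


def ellipsoid_mask(shape, spacing, center_mm, axes_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ellipsoid."""
    zc, yc, xc = _center_coords(shape, spacing)
    cz, cy, cx = center_mm
    az, ay, ax = (a / 2.0 for a in axes_mm)
    q = (
        ((zc - cz) / az)[:, None, None] ** 2
        + ((yc - cy) / ay)[None, :, None] ** 2
        + ((xc - cx) / ax)[None, None, :] ** 2
    )
    return q <= 1.0


def fat_reference_mask(shape, margin: int = 2, size: int = 6) -> np.ndarray:
    """Reference ROI in the guaranteed-fat corner nearest the origin."""
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, margin + size) for _ in range(3))
    mask[sl] = True
    return mask


def render_exam(
    lesion: LesionSpec,
    acq: AcquisitionSpec,
    seed=None,
    timepoint_label: str = "pre",
) -> DynamicExam:
    """Render the four-phase volume stack for one lesion.

    Raises ``ValueError`` when the lesion does not fit inside the grid with a
    one-voxel margin. The fat-reference corner (see
    :func:`fat_reference_mask`) is kept free of glandular blobs so it stays a
    valid unenhancing reference.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in acq.grid_shape)
    extent = acq.extent_mm
    center = (
        tuple(extent / 2.0) if lesion.center is None else tuple(map(float, lesion.center))
    )
    for c, a, e in zip(center, lesion.axes, extent):
        if c - a / 2.0 < acq.voxel_size or c + a / 2.0 > e - acq.voxel_size:
            raise ValueError("lesion does not fit inside the grid")
    if lesion.baseline_hu <= acq.fat_hu:
        raise ValueError("lesion baseline attenuation must exceed the fat background")

    background = np.full(shape, acq.fat_hu, dtype=np.float32)
    if acq.n_gland_blobs:
        # unenhancing glandular texture, kept out of the fat-reference octant
        for _ in range(acq.n_gland_blobs):
            bc = rng.uniform(0.35, 0.9, size=3) * extent
            baxes = rng.uniform(5.0, 15.0, size=3)
            background[ellipsoid_mask(shape, acq.spacing, bc, baxes)] = acq.gland_hu

    lesion_mask = ellipsoid_mask(shape, acq.spacing, center, lesion.axes)
    base_corr = lesion.baseline_hu - acq.fat_hu
    fracs = lesion.enhancement_fractions(acq.phase_times)
    scales = np.concatenate(([1.0], 1.0 + (lesion.peak_ratio - 1.0) * fracs))

    volumes = np.empty((len(acq.phase_times),) + shape, dtype=np.float32)
    for i, s in enumerate(scales):
        vol = background.copy()
        vol[lesion_mask] = acq.fat_hu + base_corr * s
        if acq.noise_sd > 0:
            vol += rng.normal(0.0, acq.noise_sd, size=shape).astype(np.float32)
        volumes[i] = vol
    return DynamicExam(volumes, acq.spacing, acq.phase_times, timepoint_label, lesion)


# --------------------------------------------------------------------------
# sampling


def _trunc_normal(rng, mean, sd, lo, hi):
    """Rejection-sampled truncated normal (bounds several sd out, so cheap)."""
    if hi - lo < 1e-9:
        return float(lo)
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal bounds too tight")  # pragma: no cover


def sample_lesion(params: CohortParams, rng, acq: AcquisitionSpec) -> LesionSpec:
    """Draw one pre-treatment lesion from the cohort distributions."""
    d_hi = min(params.diameter_bounds[1], float(acq.extent_mm.min()) - 6 * acq.voxel_size)
    d1 = _trunc_normal(rng, *params.diameter, params.diameter_bounds[0], d_hi)
    r2, r3 = rng.uniform(*params.axis_ratio_range, size=2)
    # longest axis in-plane (row axis); through-plane and second in-plane shorter
    axes = (d1 * r3, d1, d1 * r2)  # (slice, row, column) diameters
    baseline = _trunc_normal(rng, *params.baseline_hu, *params.baseline_hu_bounds)
    ratio = _trunc_normal(rng, *params.peak_ratio, *params.peak_ratio_bounds)
    t_peak = float(rng.choice(params.t_peak_choices, p=params.t_peak_probs))

    post = np.asarray(acq.phase_times, float)[1:]
    f60 = _trunc_normal(rng, *params.frac60, *params.frac60_bounds)
    washout = 0.0
    fracs = np.ones_like(post)
    for i, t in enumerate(post):
        if t < t_peak:
            fracs[i] = f60 if i == 0 else _trunc_normal(rng, *params.frac120, f60, 1.0)
    if t_peak < post[-1]:
        washout = float(rng.uniform(*params.washout_frac_range))
        fracs[post > t_peak] = 1.0 - washout
    return LesionSpec(
        axes=axes,
        baseline_hu=baseline,
        peak_ratio=ratio,
        t_peak=t_peak,
        washout_frac=washout,
        enh_fracs=tuple(fracs),
    )


def _shrunk_lesion(lesion: LesionSpec, shrink: float, enh_factor: float) -> LesionSpec:
    axes = tuple(a * shrink for a in lesion.axes)
    ratio = 1.0 + (lesion.peak_ratio - 1.0) * max(enh_factor, 0.0)
    return replace(lesion, axes=axes, peak_ratio=ratio)


def _sample_patient(response: str, params: CohortParams, rng, acq: AcquisitionSpec,
                    patient_id: str):
    """Shared draw: covariate record plus per-timepoint ground-truth lesions."""
    if response not in ("pCR", "non-pCR"):
        raise ValueError("response must be 'pCR' or 'non-pCR'")
    is_pcr = response == "pCR"
    group = params.pcr_group if is_pcr else params.non_pcr_group
    lesion0 = sample_lesion(params, rng, acq)
    lesions = {"pre": lesion0}
    for tp, shrink_d, enh_d in (
        ("mid", group.shrink_mid, group.enh_mid),
        ("late", group.shrink_late, group.enh_late),
    ):
        s = float(np.clip(rng.normal(*shrink_d), 0.02, 1.5))
        e = float(np.clip(rng.normal(*enh_d), 0.0, 1.5))
        lesions[tp] = _shrunk_lesion(lesion0, s, e)

    age_dist = params.age_pcr if is_pcr else params.age_non_pcr
    age = _trunc_normal(rng, *age_dist, *params.age_bounds)
    side = "right" if rng.random() < params.p_right else "left"
    hormone_pos = rng.random() < params.p_hormone_positive
    if hormone_pos:
        er = rng.random() < 0.85
        pr = True if not er else rng.random() < 0.7
    else:
        er = pr = False
    her2 = rng.random() < params.p_her2_positive
    ki67 = "high" if rng.random() < params.p_ki67_high else "low"
    if er or pr:
        subtype = "luminal"
    elif her2:
        subtype = "her2_enriched"
    else:
        subtype = "triple_negative"
    grade = 5 if is_pcr else 1 + int(rng.choice(4, p=params.non_pcr_grade_probs))
    record = PatientRecord(
        patient_id=patient_id,
        age=round(age, 1),
        side=side,
        er=er,
        pr=pr,
        her2=her2,
        ki67_class=ki67,
        subtype=subtype,
        mpg_grade=grade,
        pcr=is_pcr,
    )
    return record, lesions


def simulate_patient(
    response: str,
    params: CohortParams,
    acq: AcquisitionSpec,
    seed=None,
    patient_id: str = "P000",
    render: bool = True,
) -> PatientSeries:
    """Simulate one patient: covariates plus pre/mid/late dynamic exams."""
    rng = np.random.default_rng(seed)
    record, lesions = _sample_patient(response, params, rng, acq, patient_id)
    series = PatientSeries(record=record, lesions=lesions)
    if render:
        for tp in TIMEPOINTS:
            series.exams[tp] = render_exam(lesions[tp], acq, seed=rng, timepoint_label=tp)
    return series


def simulate_cohort(
    params: CohortParams,
    acq: AcquisitionSpec,
    seed=None,
    render: bool = True,
) -> List[PatientSeries]:
    """Simulate a cohort with independent per-patient substreams."""
    if params.n_patients < 2:
        raise ValueError("n_patients must be at least 2")
    master = np.random.SeedSequence(seed)
    children = master.spawn(params.n_patients + 1)
    label_rng = np.random.default_rng(children[0])
    responses = np.where(
        label_rng.random(params.n_patients) < params.pcr_prevalence, "pCR", "non-pCR"
    )
    cohort = []
    for i, (resp, ss) in enumerate(zip(responses, children[1:])):
        cohort.append(
            simulate_patient(
                str(resp), params, acq, seed=ss, patient_id=f"P{i:03d}", render=render
            )
        )
    return cohort


# --------------------------------------------------------------------------
# analytic (tabular) feature path


def _ellipsoid_surface(axes_mm) -> float:
    """Thomsen approximation of the ellipsoid surface area (mm^2)."""
    a, b, c = (x / 2.0 for x in axes_mm)
    p = 1.6075
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * math.pi * s ** (1.0 / p)


def true_features(
    lesion: LesionSpec,
    phase_times: Sequence[float] = (0.0, 60.0, 120.0, 180.0),
    fat_hu: float = -100.0,
) -> Dict[str, float]:
    """Analytic feature values implied by a lesion spec (no voxels).

    Column names match the extraction pipeline's cohort table.
    """
    base = lesion.baseline_hu - fat_hu
    delta = lesion.delta_hu_true(phase_times, fat_hu)
    post = np.asarray(phase_times, float)[1:]
    i_max = int(np.argmax(delta))
    t_max = float(post[i_max])
    ratio = (base + float(delta[i_max])) / base
    wash_in = 100.0 * (max(float(delta[i_max]), 0.0) / base) / t_max
    if i_max == len(post) - 1:
        washout = 0.0
    else:
        washout = (
            100.0 * ((float(delta[i_max]) - float(delta[-1])) / base) / (post[-1] - t_max)
        )
    feats = {
        "lesion_density_hu": lesion.baseline_hu,
        "max_enh_ratio": ratio,
        "wash_in_rate": wash_in,
        "washout_rate": washout,
        "diameter_mm": float(max(lesion.axes[1], lesion.axes[2])),
        "calc_volume_mm3": math.pi / 6.0 * float(np.prod(lesion.axes)),
        "seg_volume_mm3": math.pi / 6.0 * float(np.prod(lesion.axes)),
        "seg_surface_mm2": _ellipsoid_surface(lesion.axes),
    }
    for t, d in zip(post, delta):
        minutes = int(round(t / 60.0))
        name = {1: "one_min_enh", 2: "two_min_enh", 3: "three_min_enh"}.get(minutes)
        if name:
            feats[name] = float(d)
    return feats


def simulate_cohort_table(
    params: CohortParams,
    seed=None,
    acq: Optional[AcquisitionSpec] = None,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> pd.DataFrame:
    """Fast path: cohort table of analytically known features per timepoint.

    Used for statistical power / selection studies where rendering voxels for
    every exam would dominate the budget; shares the sampling routine with
    :func:`simulate_cohort`.
    """
    acq = acq or AcquisitionSpec()
    cohort = simulate_cohort(params, acq, seed=seed, render=False)
    rows = []
    for series in cohort:
        rec = series.record
        base_vol = math.pi / 6.0 * float(np.prod(series.lesions["pre"].axes))
        base_surf = _ellipsoid_surface(series.lesions["pre"].axes)
        for tp in timepoints:
            feats = true_features(series.lesions[tp], acq.phase_times, acq.fat_hu)
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
            }
            row.update(feats)
            row["seg_volume_reduction_pct"] = 100.0 * (1.0 - feats["seg_volume_mm3"] / base_vol)
            row["seg_surface_reduction_pct"] = 100.0 * (1.0 - feats["seg_surface_mm2"] / base_surf)
            rows.append(row)
    return pd.DataFrame(rows)
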