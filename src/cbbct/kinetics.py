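"""Fat-normalized enhancement and three-phase kinetic parameters.

All enhancement values are corrected against a fat reference ROI measured on
the same slice, which cancels per-sweep attenuation drift:

    delta_HU(t) = (HU_lesion_post - HU_fat_post) - (HU_lesion_pre - HU_fat_pre)

The three curve summaries use the pre-contrast fat-corrected lesion
attenuation ``base = HU_lesion_pre - HU_fat_pre`` as the normalizer:

* maximum enhancement ratio = (base + max delta_HU) / base (dimensionless;
  1 means no net enhancement),
* wash-in rate = 100 * (max delta_HU / base) / T_peak, in percent of
  baseline per second,
* washout rate = 100 * ((delta_HU_peak - delta_HU_final) / base) /
  (T_final - T_peak), zero for persistent (peak-at-final-phase) curves.

ROI convention: the lesion is measured on the axial slice with maximal
lesion-mask area (ties broken toward the lower slice index); optionally the
lowest decile of pre-contrast voxels is excluded to approximate the reading
practice of avoiding visible necrosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .phantom import DynamicExam

__all__ = [
    "RoiMeasurement",
    "EnhancementCurve",
    "KineticFeatures",
    "compute_delta_hu",
    "build_curve",
    "max_enhancement_ratio",
    "wash_in_rate",
    "washout_rate",
    "kinetic_features",
]


@dataclass(frozen=True)
class RoiMeasurement:
    """Paired lesion / fat-reference ROI means for one post-contrast phase."""

    hu_lesion_pre: float
    hu_lesion_post: float
    hu_fat_pre: float
    hu_fat_post: float


def compute_delta_hu(m: RoiMeasurement) -> float:
    """Fat-corrected lesion enhancement for one phase."""
    return (m.hu_lesion_post - m.hu_fat_post) - (m.hu_lesion_pre - m.hu_fat_pre)


@dataclass(frozen=True)
class EnhancementCurve:
    """Fat-corrected enhancement course of one exam.

    ``base_corrected`` is the pre-contrast fat-corrected lesion attenuation;
    ``delta_hu`` holds one value per post-contrast phase at ``phase_times``.
    """

    base_corrected: float
    delta_hu: Tuple[float, ...]
    phase_times: Tuple[float, ...]  # post-contrast times, s

    def __post_init__(self) -> None:
        if len(self.delta_hu) != len(self.phase_times):
            raise ValueError("one delta_hu per post-contrast phase required")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase_times must be strictly increasing")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.delta_hu))  # earliest phase on ties

    @property
    def t_peak(self) -> float:
        return float(self.phase_times[self.peak_index])


@dataclass(frozen=True)
class KineticFeatures:
    one_min_enh: float
    two_min_enh: float
    three_min_enh: float
    max_enh_ratio: float
    wash_in_rate: float
    washout_rate: float


def _largest_section(mask: np.ndarray) -> int:
    """Index of the axial (axis-0) slice with maximal mask area."""
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    return int(np.argmax(areas))  # argmax -> lowest index on ties


def build_curve(
    exam: DynamicExam,
    lesion_mask: np.ndarray,
    fat_mask: np.ndarray,
    exclude_necrosis: bool = True,
) -> EnhancementCurve:
    """Measure the enhancement curve of one exam.

    Lesion and fat ROI means are taken on the lesion's largest axial section
    (falling back to the whole fat mask when it is empty on that slice). With
    ``exclude_necrosis`` the lowest decile of pre-contrast lesion voxels is
    dropped from the ROI; the same voxel set is then used at every phase.
    """
    lesion_mask = np.asarray(lesion_mask, bool)
    fat_mask = np.asarray(fat_mask, bool)
    if lesion_mask.shape != exam.shape or fat_mask.shape != exam.shape:
        raise ValueError("mask shape must match the exam volumes")
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    if not fat_mask.any():
        raise ValueError("fat mask is empty")

    exam = exam.sorted_by_time()
    pre = exam.phase_volumes[0]

    k = _largest_section(lesion_mask)
    roi = np.zeros_like(lesion_mask)
    roi[k] = lesion_mask[k]
    pre_vals = pre[roi]
    if exclude_necrosis and pre_vals.size >= 10:
        cutoff = np.quantile(pre_vals, 0.10)
        keep = pre[roi] >= cutoff
        idx = np.where(roi)
        roi = np.zeros_like(roi)
        roi[idx[0][keep], idx[1][keep], idx[2][keep]] = True

    fat_roi = np.zeros_like(fat_mask)
    fat_roi[k] = fat_mask[k]
    if not fat_roi.any():
        fat_roi = fat_mask

    hu_lesion_pre = float(pre[roi].mean())
    hu_fat_pre = float(pre[fat_roi].mean())
    deltas = []
    for vol in exam.phase_volumes[1:]:
        m = RoiMeasurement(
            hu_lesion_pre=hu_lesion_pre,
            hu_lesion_post=float(vol[roi].mean()),
            hu_fat_pre=hu_fat_pre,
            hu_fat_post=float(vol[fat_roi].mean()),
        )
        deltas.append(compute_delta_hu(m))
    return EnhancementCurve(
        base_corrected=hu_lesion_pre - hu_fat_pre,
        delta_hu=tuple(deltas),
        phase_times=tuple(np.asarray(exam.phase_times, float)[1:]),
    )


def _check_base(c: EnhancementCurve) -> None:
    if c.base_corrected <= 0:
        raise ValueError(
            "non-physical ROI: pre-contrast fat-corrected attenuation must be positive"
        )


def max_enhancement_ratio(c: EnhancementCurve) -> float:
    """Peak corrected attenuation relative to the pre-contrast corrected
    attenuation; 1.0 for a non-enhancing lesion."""
    _check_base(c)
    return (c.base_corrected + max(c.delta_hu)) / c.base_corrected


def wash_in_rate(c: EnhancementCurve) -> float:
    """Rate of rise to peak, percent of baseline per second (0 when the curve
    never rises above baseline)."""
    _check_base(c)
    peak = max(c.delta_hu)
    if peak <= 0:
        return 0.0
    return 100.0 * (peak / c.base_corrected) / c.t_peak


def washout_rate(c: EnhancementCurve) -> float:
    """Rate of decline from the peak phase to the final phase, percent of
    baseline per second; 0 for persistent curves (peak at the final phase)."""
    _check_base(c)
    i = c.peak_index
    if i == len(c.delta_hu) - 1:
        return 0.0
    drop = c.delta_hu[i] - c.delta_hu[-1]
    return 100.0 * (drop / c.base_corrected) / (c.phase_times[-1] - c.phase_times[i])


def kinetic_features(c: EnhancementCurve) -> KineticFeatures:
    """Bundle the per-minute enhancements and the three curve summaries."""
    by_minute = {}
    for t, d in zip(c.phase_times, c.delta_hu):
        by_minute[int(round(t / 60.0))] = float(d)
    return KineticFeatures(
        one_min_enh=by_minute.get(1, float("nan")),
        two_min_enh=by_minute.get(2, float("nan")),
        three_min_enh=by_minute.get(3, float("nan")),
        max_enh_ratio=max_enhancement_ratio(c),
        wash_in_rate=wash_in_rate(c),
        washout_rate=washout_rate(c),
    )
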