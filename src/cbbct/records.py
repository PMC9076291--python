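"""Patient-level record containers shared by the phantom and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import DynamicExam, LesionSpec

TIMEPOINTS = ("pre", "mid", "late")

SUBTYPES = ("luminal", "her2_enriched", "triple_negative")


@dataclass
class PatientRecord:
    """Clinical covariates and the histopathologic response label.

    ``pcr`` is True exactly when ``mpg_grade`` is 5 (no identifiable residual
    invasive tumor on the Miller-Payne scale); grades 1-4 are non-responders.
    ``ki67_class`` dichotomizes the proliferation index at 14%.
    """

    patient_id: str
    age: float
    side: str  # "left" | "right"
    er: bool
    pr: bool
    her2: bool
    ki67_class: str  # "high" (>14%) | "low" (<=14%)
    subtype: str
    mpg_grade: int
    pcr: bool

    def __post_init__(self) -> None:
        if self.mpg_grade not in (1, 2, 3, 4, 5):
            raise ValueError(f"Miller-Payne grade must be 1..5, got {self.mpg_grade}")
        if self.pcr != (self.mpg_grade == 5):
            raise ValueError("pcr label inconsistent with Miller-Payne grade")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")

    @property
    def hormone_status(self) -> str:
        return "positive" if (self.er or self.pr) else "negative"


@dataclass
class PatientSeries:
    """One simulated (or loaded) patient: covariates plus exams by timepoint.

    ``lesions`` carries the ground-truth lesion parameters per timepoint when
    the series comes from the phantom; it is empty for loaded data.
    """

    record: PatientRecord
    exams: Dict[str, "DynamicExam"] = field(default_factory=dict)
    lesions: Dict[str, "LesionSpec"] = field(default_factory=dict)

    def timepoints(self):
        return tuple(t for t in TIMEPOINTS if t in self.exams)
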