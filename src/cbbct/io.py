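"""NIfTI volume and CSV manifest input/output.

One ``.nii.gz`` file per phase, spacing carried in the affine; masks as
uint8. The cohort manifest is a CSV with one row per
(patient, timepoint, phase) plus covariate columns, which is enough to
rebuild :class:`~cbbct.records.PatientSeries` objects for extraction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import DynamicExam
from .records import PatientRecord, PatientSeries, TIMEPOINTS

__all__ = ["save_volume", "load_volume", "save_exam", "load_exam",
           "write_cohort", "read_cohort"]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(volume: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_exam(exam: DynamicExam, out_dir, stem: str) -> List[str]:
    """Write one file per phase; returns the relative file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for t, vol in zip(exam.phase_times, exam.phase_volumes):
        name = f"{stem}_t{int(t):03d}.nii.gz"
        save_volume(vol, exam.spacing, out / name)
        names.append(name)
    return names


def load_exam(paths, phase_times, timepoint_label: str) -> DynamicExam:
    vols, spacing = [], None
    for p in paths:
        v, sp = load_volume(p)
        vols.append(v)
        spacing = sp
    return DynamicExam(np.stack(vols), spacing, tuple(phase_times), timepoint_label)


def write_cohort(cohort: Iterable[PatientSeries], out_dir) -> Path:
    """Write every exam volume plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for series in cohort:
        rec = series.record
        for tp in series.timepoints():
            exam = series.exams[tp]
            names = save_exam(exam, out / "volumes", f"{rec.patient_id}_{tp}")
            for t, name in zip(exam.phase_times, names):
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "timepoint": tp,
                        "phase_time_s": float(t),
                        "file": f"volumes/{name}",
                        "age": rec.age,
                        "side": rec.side,
                        "er": rec.er,
                        "pr": rec.pr,
                        "her2": rec.her2,
                        "ki67_class": rec.ki67_class,
                        "subtype": rec.subtype,
                        "mpg_grade": rec.mpg_grade,
                        "pcr": rec.pcr,
                    }
                )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> List[PatientSeries]:
    """Rebuild patient series from a manifest written by :func:`write_cohort`
    (or hand-authored to the same schema)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cohort = []
    for pid, pdf in df.groupby("patient_id", sort=True):
        first = pdf.iloc[0]
        record = PatientRecord(
            patient_id=str(pid),
            age=float(first["age"]),
            side=str(first["side"]),
            er=bool(first["er"]),
            pr=bool(first["pr"]),
            her2=bool(first["her2"]),
            ki67_class=str(first["ki67_class"]),
            subtype=str(first["subtype"]),
            mpg_grade=int(first["mpg_grade"]),
            pcr=bool(first["pcr"]),
        )
        series = PatientSeries(record=record)
        for tp, tdf in pdf.groupby("timepoint"):
            tdf = tdf.sort_values("phase_time_s")
            series.exams[str(tp)] = load_exam(
                [root / f for f in tdf["file"]],
                tdf["phase_time_s"].tolist(),
                str(tp),
            )
        cohort.append(series)
    return cohort
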