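"""File formats: NIfTI-1 volumes, BIDS-dialect events TSV, covariate CSV.

Volumes are written with a 3 mm isotropic affine by default.  Events
files use the BIDS dialect (tab-separated ``onset``, ``duration``,
``trial_type`` columns).  Feature matrices are stored as a values CSV
with a row-metadata CSV sidecar plus the mask volume.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from mvgpc.errors import InvalidParameterError
from mvgpc.first_level import FeatureMatrix
from mvgpc.synthetic_data import CONDITIONS, Event, EventSchedule, SubjectRecord

DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = DEFAULT_AFFINE if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_events(schedule: EventSchedule, path) -> None:
    frame = pd.DataFrame(
        {
            "onset": schedule.onsets,
            "duration": schedule.durations,
            "trial_type": schedule.conditions,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def load_events(path, total_duration: float | None = None, seed: int = 0) -> EventSchedule:
    frame = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(frame.columns):
        raise InvalidParameterError(f"events file needs columns {sorted(required)}")
    events = tuple(
        Event(float(r.onset), float(r.duration), str(r.trial_type))
        for r in frame.itertuples()
    )
    if total_duration is None:
        total_duration = float(frame.onset.iloc[-1] + frame.duration.iloc[-1] + 16.0)
    return EventSchedule(events=events, total_duration=total_duration, seed=seed)


def save_cohort(records: list[SubjectRecord], out_dir) -> None:
    """Beta volumes as ``<subject>_<condition>.nii.gz`` plus covariates.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for cond, vol in rec.betas.items():
            save_volume(out / f"{rec.subject_id}_{cond}.nii.gz", vol)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "medication_load": rec.medication_load,
                "substance_history": rec.substance_history,
            }
        )
    pd.DataFrame(rows).to_csv(out / "covariates.csv", index=False)


def load_cohort(in_dir) -> list[SubjectRecord]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "covariates.csv")
    records = []
    for row in table.itertuples():
        betas = {
            cond: load_volume(in_dir / f"{row.subject_id}_{cond}.nii.gz")
            for cond in CONDITIONS
        }
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                medication_load=float(row.medication_load),
                substance_history=int(row.substance_history),
                betas=betas,
            )
        )
    return records


def save_features(features: FeatureMatrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(features.values).to_csv(f"{prefix}_values.csv", index=False)
    features.rows.to_csv(f"{prefix}_rows.csv", index=False)
    save_volume(f"{prefix}_mask.nii.gz", features.mask.astype(float))


def load_features(prefix) -> FeatureMatrix:
    values = pd.read_csv(f"{prefix}_values.csv").to_numpy(float)
    rows = pd.read_csv(f"{prefix}_rows.csv")
    mask = load_volume(f"{prefix}_mask.nii.gz") > 0.5
    return FeatureMatrix(values=values, rows=rows, mask=mask)
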