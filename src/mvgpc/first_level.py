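"""First-level modeling: HRF, design matrix, GLM fit, feature extraction.

Condition regressors are stimulus boxcars convolved with a double-gamma
canonical HRF on a 0.1 s microtime grid, then sampled at scan onsets.
The GLM is ordinary least squares per voxel; condition coefficient
volumes, read through a brain mask in a fixed voxel order, form the
examples-by-voxels feature matrix used by the classifiers downstream
(whole-brain features, no feature selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from mvgpc.errors import (
    InvalidParameterError,
    MissingDataError,
    RankError,
    ShapeError,
)
from mvgpc.synthetic_data import CONDITIONS, EventSchedule, SubjectRecord

#: Microtime resolution (s) for boxcar/HRF convolution.
MICROTIME_DT = 0.1


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF settings (SPM-convention defaults)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0


def canonical_hrf(time_grid: np.ndarray, params: HrfParams | None = None) -> np.ndarray:
    """Double-gamma canonical HRF sampled on ``time_grid``.

    Zero at t=0, peaking near ``params.peak_delay``, normalized so the
    peak amplitude is 1 (when the grid captures a positive response).
    """
    params = params or HrfParams()
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise InvalidParameterError("time_grid is empty")
    if np.any(t < 0) or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise InvalidParameterError("time_grid must be non-negative and increasing")
    # shape = delay/dispersion + 1 puts the gamma mode exactly at the delay
    peak = gamma_dist.pdf(
        t, params.peak_delay / params.peak_dispersion + 1.0, scale=params.peak_dispersion
    )
    undershoot = gamma_dist.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion + 1.0,
        scale=params.undershoot_dispersion,
    )
    h = peak - params.undershoot_ratio * undershoot
    hmax = h.max()
    if hmax > 0:
        h = h / hmax
    return h


@dataclass(frozen=True)
class DesignMatrix:
    """Scan-by-regressor design with labeled columns."""

    values: np.ndarray
    column_labels: tuple[str, ...]
    tr: float

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_labels):
            raise ShapeError("values shape does not match column labels")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("design matrix has non-finite entries")
        if self.values.shape[0] < self.values.shape[1]:
            raise InvalidParameterError("need n_scans >= n_regressors")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.column_labels.index(label)
        except ValueError:
            raise MissingDataError(f"no design column {label!r}") from None
        return self.values[:, j]


def build_design_matrix(
    schedule: EventSchedule,
    tr: float,
    n_scans: int,
    motion: np.ndarray | None = None,
    hrf_params: HrfParams | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> DesignMatrix:
    """Condition regressors + optional motion columns + intercept.

    Each condition column is the boxcar of its events convolved with the
    canonical HRF on a 0.1 s grid and sampled at scan onsets (t = i*tr).
    """
    if tr <= 0 or n_scans < 1:
        raise InvalidParameterError("tr and n_scans must be positive")
    scan_window = n_scans * tr
    if len(schedule.events) and (
        schedule.onsets[-1] + schedule.durations[-1] > scan_window + 1e-9
    ):
        raise InvalidParameterError("schedule events fall outside the scan window")

    n_fine = int(np.ceil(scan_window / MICROTIME_DT)) + 1
    fine_t = np.arange(n_fine) * MICROTIME_DT
    hrf = canonical_hrf(np.arange(0, 32.0 + MICROTIME_DT, MICROTIME_DT), hrf_params)

    columns, labels = [], []
    scan_idx = np.round(np.arange(n_scans) * tr / MICROTIME_DT).astype(int)
    for cond in conditions:
        boxcar = np.zeros(n_fine)
        for ev in schedule.events:
            if ev.condition != cond:
                continue
            i0 = int(round(ev.onset / MICROTIME_DT))
            i1 = int(round((ev.onset + ev.duration) / MICROTIME_DT))
            boxcar[i0:i1] = 1.0
        regressor = np.convolve(boxcar, hrf)[:n_fine]
        columns.append(regressor[scan_idx])
        labels.append(cond)
    del fine_t

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ShapeError("motion rows must equal n_scans")
        for j in range(motion.shape[1]):
            columns.append(motion[:, j])
            labels.append(f"motion_{j}")

    columns.append(np.ones(n_scans))
    labels.append("intercept")
    return DesignMatrix(
        values=np.column_stack(columns), column_labels=tuple(labels), tr=tr
    )


def fit_glm(timeseries: np.ndarray, design: DesignMatrix) -> dict[str, np.ndarray]:
    """Per-voxel OLS; returns one coefficient volume per condition column.

    Raises :class:`RankError` if the design is rank deficient.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 4:
        raise ShapeError("timeseries must be 4-D (x, y, z, t)")
    if ts.shape[-1] != design.n_scans:
        raise ShapeError(
            f"time dimension {ts.shape[-1]} != design rows {design.n_scans}"
        )
    X = design.values
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient")

    grid = ts.shape[:3]
    Y = ts.reshape(-1, design.n_scans).T  # scans x voxels
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = {}
    for j, label in enumerate(design.column_labels):
        if label in CONDITIONS:
            out[label] = coef[j].reshape(grid)
    return out


@dataclass
class FeatureMatrix:
    """Examples-by-voxels matrix with row metadata and its producing mask.

    ``rows`` has columns ``subject_id``, ``condition``, ``group`` aligned
    one-to-one with the rows of ``values``.  ``voxel_index`` holds the
    0-based flat (C-order) volume index of each feature column, making
    extraction invertible via :meth:`scatter`.
    """

    values: np.ndarray
    rows: pd.DataFrame
    mask: np.ndarray
    voxel_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.voxel_index is None:
            self.voxel_index = np.flatnonzero(self.mask.ravel())
        if self.values.shape[1] != self.voxel_index.size:
            raise ShapeError("n_voxels != mask voxel count")
        if self.values.shape[0] != len(self.rows):
            raise ShapeError("row metadata does not match value rows")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("feature matrix has non-finite entries")

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def scatter(self, vector: np.ndarray) -> np.ndarray:
        """Place a feature-space vector back into a volume (zeros elsewhere)."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_voxels,):
            raise ShapeError("vector length must equal n_voxels")
        vol = np.zeros(self.mask.size)
        vol[self.voxel_index] = vector
        return vol.reshape(self.mask.shape)

    def subset(self, row_indices: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[row_indices],
            rows=self.rows.iloc[row_indices].reset_index(drop=True),
            mask=self.mask,
            voxel_index=self.voxel_index,
        )


def variance_mask(records: list[SubjectRecord], conditions=CONDITIONS) -> np.ndarray:
    """Default mask: voxels with nonzero variance across all images."""
    stack = np.stack([r.betas[c] for r in records for c in conditions])
    return stack.var(axis=0) > 0


def extract_features(
    records: list[SubjectRecord],
    mask: np.ndarray,
    conditions=CONDITIONS,
) -> FeatureMatrix:
    """One row per (subject, condition), voxels in ascending flat order."""
    if not records:
        raise InvalidParameterError("no subject records given")
    mask = np.asarray(mask).astype(bool)
    voxel_index = np.flatnonzero(mask.ravel())
    if voxel_index.size == 0:
        raise InvalidParameterError("mask selects no voxels")

    values, meta = [], []
    for rec in records:
        for cond in conditions:
            if cond not in rec.betas:
                raise MissingDataError(
                    f"subject {rec.subject_id} lacks condition {cond!r}"
                )
            vol = rec.betas[cond]
            if vol.shape != mask.shape:
                raise ShapeError(
                    f"subject {rec.subject_id} volume shape {vol.shape} "
                    f"!= mask shape {mask.shape}"
                )
            values.append(vol.ravel()[voxel_index])
            meta.append((rec.subject_id, cond, rec.group))
    rows = pd.DataFrame(meta, columns=["subject_id", "condition", "group"])
    return FeatureMatrix(
        values=np.array(values), rows=rows, mask=mask, voxel_index=voxel_index
    )
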