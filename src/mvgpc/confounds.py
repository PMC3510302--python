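"""Covariate residualization via the residual-forming projector.

Nuisance covariates (e.g., medication load, substance-history flag) are
removed from feature rows with R = I - C (C'C)^+ C', either estimated on
training rows only (leakage-free, the cross-validation default) or
applied to the whole sample at once.  Covariates are per-subject; their
rows are duplicated across each subject's examples so the two tables
stay aligned.  Condition labels never enter C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mvgpc.errors import AlignmentError, InvalidParameterError
from mvgpc.first_level import FeatureMatrix

RESIDUALIZE_MODES = ("train_only", "whole_sample")


@dataclass(frozen=True)
class CovariateMatrix:
    """Per-example covariate rows aligned with a FeatureMatrix."""

    values: np.ndarray
    labels: tuple[str, ...]
    includes_intercept: bool = False

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[1] != len(self.labels):
            raise InvalidParameterError("covariate values/labels mismatch")
        if v.shape[1] == 0:
            raise InvalidParameterError("covariate matrix is empty")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("covariates contain non-finite entries")

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    def with_intercept(self) -> "CovariateMatrix":
        if self.includes_intercept:
            return self
        return CovariateMatrix(
            values=np.column_stack([self.values, np.ones(self.n_examples)]),
            labels=self.labels + ("intercept",),
            includes_intercept=True,
        )


def intercept_only(n_examples: int) -> CovariateMatrix:
    """Intercept-only covariates (residualization = column centering)."""
    if n_examples < 1:
        raise InvalidParameterError("n_examples must be >= 1")
    return CovariateMatrix(
        values=np.ones((n_examples, 1)), labels=("intercept",), includes_intercept=True
    )


def covariates_for(
    features: FeatureMatrix, table: pd.DataFrame, columns=("medication_load", "substance_history")
) -> CovariateMatrix:
    """Expand a per-subject covariate table to per-example rows.

    ``table`` must be indexed (or indexable) by ``subject_id`` and carry
    one row per subject appearing in ``features.rows``.
    """
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    missing = set(features.rows["subject_id"]) - set(table.index)
    if missing:
        raise AlignmentError(f"covariate table missing subjects: {sorted(missing)}")
    expanded = table.loc[features.rows["subject_id"], list(columns)].to_numpy(float)
    return CovariateMatrix(values=expanded, labels=tuple(columns))


def residual_forming_matrix(C: CovariateMatrix | np.ndarray) -> np.ndarray:
    """R = I - C (C'C)^+ C'.

    Symmetric, idempotent, annihilates the column space of C; robust to
    linearly dependent covariate columns through the pseudo-inverse.
    """
    values = C.values if isinstance(C, CovariateMatrix) else np.asarray(C, dtype=float)
    if values.ndim != 2 or values.shape[1] == 0 or values.shape[0] == 0:
        raise InvalidParameterError("covariate matrix is empty")
    if values.shape[0] < values.shape[1]:
        raise InvalidParameterError("need n_examples >= n_covariates")
    n = values.shape[0]
    return np.eye(n) - values @ np.linalg.pinv(values)


def residualize(
    features: FeatureMatrix,
    covariates: CovariateMatrix,
    mode: str = "train_only",
    train_rows: np.ndarray | None = None,
) -> FeatureMatrix:
    """Remove covariate-explained variance from feature rows.

    ``train_only``: regression coefficients are estimated on
    ``train_rows`` and the fitted covariate effect is subtracted from
    all rows (no test-to-train leakage).  ``whole_sample``: the
    projector R is applied to the full matrix.  An intercept column is
    always appended before fitting.
    """
    if mode not in RESIDUALIZE_MODES:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if covariates.n_examples != features.n_examples:
        raise AlignmentError(
            f"covariate rows ({covariates.n_examples}) != feature rows "
            f"({features.n_examples})"
        )
    C = covariates.with_intercept().values
    X = features.values

    if mode == "whole_sample":
        resid = residual_forming_matrix(C) @ X
    else:
        if train_rows is None:
            train_rows = np.arange(features.n_examples)
        train_rows = np.asarray(train_rows)
        if train_rows.size == 0:
            raise InvalidParameterError("train_rows is empty")
        B = np.linalg.pinv(C[train_rows]) @ X[train_rows]
        resid = X - C @ B

    return FeatureMatrix(
        values=resid,
        rows=features.rows.copy(),
        mask=features.mask,
        voxel_index=features.voxel_index,
    )
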