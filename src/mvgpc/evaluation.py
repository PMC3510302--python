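"""Cross-validated classifier evaluation and permutation significance.

Within-group: leave-one-subject-out (LOSO) cross-validation of the
condition classifier; each fold holds out both examples (one per class)
of one subject.  Between-group: leave-one-pair-out (LOPO)
cross-validation holding out one matched subject pair per fold.

Class assignment uses the 0.5 threshold on the predictive probability:
strictly above 0.5 is class 1; 0.5 or below is class 2.  The headline
accuracy is the balanced accuracy, the arithmetic mean of the
true-positive (class 1) and true-negative (class 2) rates.  Permutation
p-values use the add-one formula ``(1 + #{perm >= observed}) / (1 + n)``
and therefore can never be zero.

For speed with linear kernels, per-fold Gram matrices are precomputed
once and reused across permutations (label permutations do not change
the kernel, and covariates do not depend on condition labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mvgpc.confounds import CovariateMatrix, intercept_only, residualize
from mvgpc.errors import (
    InvalidParameterError,
    MissingDataError,
    PairingError,
)
from mvgpc.first_level import FeatureMatrix
from mvgpc.gpc import (
    AMPLITUDE_GRID,
    KernelOptions,
    laplace_fit_gram,
    laplace_predict_gram,
)


class DegeneratePermutationWarning(UserWarning):
    """The permutation scheme cannot produce distinct label patterns."""


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation settings.

    The CV default fixes the kernel amplitude at 1 on a trace-normalized
    Gram matrix; set ``kernel.amplitude="grid"`` for per-fold evidence
    grid search (slower).
    """

    kernel: KernelOptions = field(
        default_factory=lambda: KernelOptions(amplitude=1.0, normalize=True)
    )
    residualize_mode: str = "train_only"
    n_permutations: int = 0
    seed: int = 0


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    contrast: str
    condition: str
    probability_class1: float
    fold_index: int


@dataclass
class WithinGroupResult:
    group: str
    contrast: tuple[str, str]  # (class 1 condition, class 2 condition)
    predictions: list[Prediction]
    accuracy: float
    tp_rate: float
    tn_rate: float
    p_value: float | None
    n_permutations: int
    seed: int


@dataclass
class BetweenGroupResult:
    group_pair: tuple[str, str]  # (class 1 group, class 2 group)
    condition: str
    predictions: list[Prediction]
    sensitivity: float
    specificity: float
    accuracy: float
    p_value: float | None
    n_permutations: int
    seed: int


def balanced_accuracy(tp_rate: float, tn_rate: float) -> float:
    """Mean of the class-1 and class-2 correct-classification rates."""
    if not (0.0 <= tp_rate <= 1.0 and 0.0 <= tn_rate <= 1.0):
        raise InvalidParameterError("rates must lie in [0, 1]")
    return (tp_rate + tn_rate) / 2.0


@dataclass
class _Fold:
    """Precomputed kernels for one CV fold (label independent)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    K_base: np.ndarray  # normalized train Gram, before amplitude/bias
    K_cross: np.ndarray  # (n_test, n_train), same scaling as K_base
    k_diag: np.ndarray


def _build_fold(X: np.ndarray, train_idx, test_idx, kernel: KernelOptions) -> _Fold:
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise InvalidParameterError("train/test rows overlap")  # leakage guard
    Xtr, Xte = X[train_idx], X[test_idx]
    K = Xtr @ Xtr.T
    scale = len(train_idx) / np.trace(K) if (kernel.normalize and np.trace(K) > 0) else 1.0
    return _Fold(
        train_idx=train_idx,
        test_idx=test_idx,
        K_base=scale * K,
        K_cross=scale * (Xte @ Xtr.T),
        k_diag=scale * np.einsum("ij,ij->i", Xte, Xte),
    )


def _fold_probabilities(fold: _Fold, y: np.ndarray, kernel: KernelOptions) -> np.ndarray:
    y_train = y[fold.train_idx]
    bias = kernel.bias
    if kernel.amplitude == "grid":
        best = None
        for amp in AMPLITUDE_GRID:
            fit = laplace_fit_gram(amp * fold.K_base + bias, y_train)
            if best is None or fit.log_marginal_likelihood > best[1].log_marginal_likelihood:
                best = (amp, fit)
        amp, fit = best
    else:
        amp = float(kernel.amplitude)
        fit = laplace_fit_gram(amp * fold.K_base + bias, y_train)
    return laplace_predict_gram(fit, amp * fold.K_cross + bias, amp * fold.k_diag + bias)


def _cv_probabilities(folds: list[_Fold], y: np.ndarray, kernel: KernelOptions) -> np.ndarray:
    probs = np.full(y.size, np.nan)
    for fold in folds:
        probs[fold.test_idx] = _fold_probabilities(fold, y, kernel)
    return probs


def _rates(probs: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    predicted_class1 = probs > 0.5  # ties at 0.5 go to class 2
    tp = float(np.mean(predicted_class1[y > 0]))
    tn = float(np.mean(~predicted_class1[y < 0]))
    return tp, tn


def permutation_test(
    cv_procedure,
    labels: np.ndarray,
    permute_labels,
    n_permutations: int,
    seed: int = 0,
) -> tuple[float, float]:
    """Add-one permutation p-value for a CV accuracy statistic.

    ``cv_procedure(labels) -> accuracy`` is re-run for every permuted
    label vector produced by ``permute_labels(rng, labels)``.  Returns
    ``(observed_accuracy, p_value)``.
    """
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    observed = cv_procedure(labels)
    rng = np.random.default_rng(seed)
    count = 0
    any_distinct = False
    for _ in range(n_permutations):
        permuted = permute_labels(rng, labels)
        any_distinct = any_distinct or not np.array_equal(permuted, labels)
        if cv_procedure(permuted) >= observed - 1e-12:
            count += 1
    if not any_distinct:
        warnings.warn(
            "permutation scheme never changed the labels",
            DegeneratePermutationWarning,
        )
    return observed, (1 + count) / (1 + n_permutations)


def _flip_subjects(rng: np.random.Generator, labels: np.ndarray, subject_rows) -> np.ndarray:
    """Flip the condition labels of a random subset of subjects."""
    out = labels.copy()
    for rows in subject_rows:
        if rng.random() < 0.5:
            out[rows] = -out[rows]
    return out


def loso_within_group(
    features: FeatureMatrix,
    contrast: tuple[str, str] = ("intense_happy", "neutral"),
    covariates: CovariateMatrix | None = None,
    config: CvConfig | None = None,
) -> WithinGroupResult:
    """Leave-one-subject-out classification of condition 1 vs condition 2.

    ``features`` should contain one example per (subject, condition) for
    one group; rows of other conditions are ignored.  Class 1 is
    ``contrast[0]`` (label +1).  If ``config.n_permutations`` > 0, a
    permutation p-value is computed by flipping the condition labels of
    random subject subsets and re-running the full cross-validation.
    """
    config = config or CvConfig()
    class1, class2 = contrast
    keep = features.rows["condition"].isin(contrast).to_numpy()
    feats = features.subset(np.flatnonzero(keep))
    rows = feats.rows
    subjects = list(dict.fromkeys(rows["subject_id"]))

    for sid in subjects:
        conds = set(rows.loc[rows["subject_id"] == sid, "condition"])
        if conds != {class1, class2}:
            raise MissingDataError(
                f"subject {sid} must have exactly one example of each of {contrast}"
            )
    if len(subjects) < 2:
        raise InvalidParameterError("LOSO needs at least 2 subjects")

    y = np.where(rows["condition"] == class1, 1.0, -1.0)
    if covariates is None:
        cov = intercept_only(feats.n_examples)
    else:
        if covariates.n_examples == features.n_examples:
            # covariates were aligned to the full matrix; keep contrast rows
            cov = CovariateMatrix(
                values=covariates.values[keep],
                labels=covariates.labels,
                includes_intercept=covariates.includes_intercept,
            )
        else:
            cov = covariates

    subject_rows = [
        np.flatnonzero((rows["subject_id"] == sid).to_numpy()) for sid in subjects
    ]
    if config.residualize_mode == "whole_sample":
        base = residualize(feats, cov, mode="whole_sample")
        folds = [
            _build_fold(
                base.values,
                np.setdiff1d(np.arange(len(rows)), test_rows),
                test_rows,
                config.kernel,
            )
            for test_rows in subject_rows
        ]
    else:
        folds = []
        for test_rows in subject_rows:
            train_rows = np.setdiff1d(np.arange(len(rows)), test_rows)
            res = residualize(feats, cov, mode="train_only", train_rows=train_rows)
            folds.append(_build_fold(res.values, train_rows, test_rows, config.kernel))

    def run(labels):
        probs = _cv_probabilities(folds, labels, config.kernel)
        return balanced_accuracy(*_rates(probs, labels))

    probs = _cv_probabilities(folds, y, config.kernel)
    tp, tn = _rates(probs, y)

    p_value = None
    if config.n_permutations > 0:
        _, p_value = permutation_test(
            run,
            y,
            lambda rng, labels: _flip_subjects(rng, labels, subject_rows),
            config.n_permutations,
            config.seed,
        )

    fold_of_row = np.empty(len(rows), dtype=int)
    for k, test_rows in enumerate(subject_rows):
        fold_of_row[test_rows] = k
    contrast_name = f"{class1}_vs_{class2}"
    predictions = [
        Prediction(
            subject_id=rows["subject_id"].iloc[i],
            contrast=contrast_name,
            condition=rows["condition"].iloc[i],
            probability_class1=float(probs[i]),
            fold_index=int(fold_of_row[i]),
        )
        for i in range(len(rows))
    ]
    return WithinGroupResult(
        group=str(rows["group"].iloc[0]),
        contrast=contrast,
        predictions=predictions,
        accuracy=balanced_accuracy(tp, tn),
        tp_rate=tp,
        tn_rate=tn,
        p_value=p_value,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )


def _swap_pairs(rng: np.random.Generator, labels: np.ndarray, pair_rows) -> np.ndarray:
    """Swap group labels within a random subset of matched pairs."""
    out = labels.copy()
    for rows in pair_rows:
        if rng.random() < 0.5:
            out[rows] = -out[rows]
    return out


def lopo_between_group(
    features_a: FeatureMatrix,
    features_b: FeatureMatrix,
    condition: str,
    pairing: list[tuple[str, str]] | None = None,
    covariates: CovariateMatrix | None = None,
    config: CvConfig | None = None,
) -> BetweenGroupResult:
    """Leave-one-pair-out discrimination of group A (class 1) vs group B.

    One example per subject (the given condition).  ``pairing`` maps
    subjects across groups as (subject_a, subject_b) tuples; by default
    subjects are paired by generation order, which requires equal group
    sizes.  Sensitivity is the class-1 (group A) rate, specificity the
    class-2 rate.
    """
    config = config or CvConfig()

    def one_per_subject(fm: FeatureMatrix) -> FeatureMatrix:
        keep = np.flatnonzero((fm.rows["condition"] == condition).to_numpy())
        if keep.size == 0:
            raise MissingDataError(f"no examples of condition {condition!r}")
        sub = fm.subset(keep)
        if sub.rows["subject_id"].duplicated().any():
            raise MissingDataError("multiple examples per subject for one condition")
        return sub

    fa, fb = one_per_subject(features_a), one_per_subject(features_b)
    subs_a = list(fa.rows["subject_id"])
    subs_b = list(fb.rows["subject_id"])
    if pairing is None:
        if len(subs_a) != len(subs_b):
            raise PairingError(
                "unequal group sizes require an explicit pairing"
            )
        pairing = list(zip(subs_a, subs_b))
    if (
        sorted(a for a, _ in pairing) != sorted(subs_a)
        or sorted(b for _, b in pairing) != sorted(subs_b)
    ):
        raise PairingError("pairing must be a bijection between the two groups")

    X = np.vstack([fa.values, fb.values])
    import pandas as pd

    rows = pd.concat([fa.rows, fb.rows], ignore_index=True)
    y = np.concatenate([np.ones(len(subs_a)), -np.ones(len(subs_b))])
    row_of = {sid: i for i, sid in enumerate(rows["subject_id"])}
    pair_rows = [np.array([row_of[a], row_of[b]]) for a, b in pairing]

    if covariates is not None:
        mode = config.residualize_mode
        fm_all = FeatureMatrix(values=X, rows=rows, mask=fa.mask, voxel_index=fa.voxel_index)
        if mode == "whole_sample":
            X = residualize(fm_all, covariates, mode="whole_sample").values

    folds = []
    for test_rows in pair_rows:
        train_rows = np.setdiff1d(np.arange(len(rows)), test_rows)
        folds.append(_build_fold(X, train_rows, test_rows, config.kernel))
    if len(folds) < 2:
        raise InvalidParameterError("LOPO needs at least 2 pairs")

    def run(labels):
        probs = _cv_probabilities(folds, labels, config.kernel)
        return balanced_accuracy(*_rates(probs, labels))

    probs = _cv_probabilities(folds, y, config.kernel)
    sens, spec = _rates(probs, y)

    p_value = None
    if config.n_permutations > 0:
        _, p_value = permutation_test(
            run,
            y,
            lambda rng, labels: _swap_pairs(rng, labels, pair_rows),
            config.n_permutations,
            config.seed,
        )

    fold_of_row = np.empty(len(rows), dtype=int)
    for k, test_rows in enumerate(pair_rows):
        fold_of_row[test_rows] = k
    pair_label = (str(fa.rows["group"].iloc[0]), str(fb.rows["group"].iloc[0]))
    predictions = [
        Prediction(
            subject_id=rows["subject_id"].iloc[i],
            contrast=f"{pair_label[0]}_vs_{pair_label[1]}",
            condition=condition,
            probability_class1=float(probs[i]),
            fold_index=int(fold_of_row[i]),
        )
        for i in range(len(rows))
    ]
    return BetweenGroupResult(
        group_pair=pair_label,
        condition=condition,
        predictions=predictions,
        sensitivity=sens,
        specificity=spec,
        accuracy=balanced_accuracy(sens, spec),
        p_value=p_value,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
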