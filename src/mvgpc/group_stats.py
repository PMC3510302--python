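"""Second-level inference on held-out predictive probabilities.

One-way ANOVA tests for a group effect on the per-subject predictive
probabilities for each stimulus class of a contrast; Newman-Keuls
step-down comparisons (studentized-range statistics whose critical value
depends on the span of each comparison) localize which group pairs
differ.  Probabilities for class-2 examples enter on the class-2 scale
(1 - p(class 1)) so "probability for condition X" means the same thing
for both classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from mvgpc.errors import InvalidParameterError, MissingDataError
from mvgpc.evaluation import WithinGroupResult


@dataclass(frozen=True)
class ProbabilitySample:
    """Per-subject predictive probabilities for one group and stimulus."""

    group: str
    stimulus_class: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InvalidParameterError("values must be a non-empty 1-D array")
        if np.any(v <= 0) or np.any(v >= 1):
            raise InvalidParameterError("probabilities must lie strictly in (0, 1)")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    mse: float  # mean squared error within groups


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    mean_diff: float  # |mean_i - mean_j|
    q: float
    span: int  # number of ordered means enclosed by the comparison
    critical: float
    p: float
    significant: bool


@dataclass(frozen=True)
class PosthocResult:
    comparisons: tuple[PairwiseComparison, ...]
    alpha: float
    mse: float
    df_within: int
    n_harmonic: float


def _as_arrays(samples) -> tuple[list[str], list[np.ndarray]]:
    labels, arrays = [], []
    for i, s in enumerate(samples):
        if isinstance(s, ProbabilitySample):
            labels.append(s.group)
            arrays.append(np.asarray(s.values, dtype=float))
        else:
            labels.append(f"group{i + 1}")
            arrays.append(np.asarray(s, dtype=float))
    return labels, arrays


def anova_oneway(samples) -> AnovaResult:
    """Fixed-effects one-way ANOVA.

    ``samples`` is a list of :class:`ProbabilitySample` (or plain value
    sequences).  Sums of squares are computed directly so that the
    within-group mean square is available for post-hoc tests.
    """
    labels, groups = _as_arrays(samples)
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    for lab, g in zip(labels, groups):
        if g.size < 2:
            raise InvalidParameterError(f"group {lab} has fewer than 2 values")

    all_values = np.concatenate(groups)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(groups)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        F = 0.0 if ms_between == 0.0 else np.inf
    else:
        F = ms_between / ms_within
    p = float(f_dist.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=p if np.isfinite(F) else 0.0,
        group_means={lab: float(g.mean()) for lab, g in zip(labels, groups)},
        mse=float(ms_within),
    )


@lru_cache(maxsize=512)
def _q_critical(alpha: float, span: int, df: int) -> float:
    return float(studentized_range.ppf(1.0 - alpha, span, df))


def newman_keuls(samples, alpha: float = 0.05, compute_p: bool = True) -> PosthocResult:
    """Step-down studentized-range comparisons of ordered group means.

    Each pair is tested with q = |mean_i - mean_j| / sqrt(MSE / n) at a
    critical value depending on the span (number of ordered means the
    comparison encloses).  The step-down stopping rule applies: if a
    wider range is not significant, every comparison nested inside it is
    declared not significant regardless of its own q.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    labels, groups = _as_arrays(samples)
    anova = anova_oneway(samples)
    sizes = np.array([g.size for g in groups], dtype=float)
    if np.unique(sizes).size > 1:
        warnings.warn(
            "unequal group sizes: using the harmonic mean n for the "
            "studentized-range standard error",
            UserWarning,
        )
    n_h = sizes.size / np.sum(1.0 / sizes)
    se = np.sqrt(anova.mse / n_h)

    order = np.argsort([g.mean() for g in groups])
    sorted_labels = [labels[i] for i in order]
    sorted_means = [groups[i].mean() for i in order]
    k = len(groups)

    raw: dict[tuple[int, int], dict] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = sorted_means[j] - sorted_means[i]
            if se == 0.0:
                q = np.inf if diff > 0 else 0.0
            else:
                q = diff / se
            span = j - i + 1
            crit = _q_critical(alpha, span, anova.df_within)
            if not compute_p:
                p = np.nan
            elif np.isfinite(q):
                p = float(studentized_range.sf(q, span, anova.df_within))
            else:
                p = 0.0
            raw[(i, j)] = dict(diff=diff, q=q, span=span, crit=crit, p=p)

    # step-down: widest spans first; a non-significant range blocks subranges
    decisions: dict[tuple[int, int], bool] = {}
    for span in range(k, 1, -1):
        for (i, j), info in raw.items():
            if info["span"] != span:
                continue
            blocked = any(
                not decisions[(a, b)]
                for (a, b) in decisions
                if a <= i and j <= b and (b - a) > (j - i)
            )
            decisions[(i, j)] = (not blocked) and bool(info["q"] > info["crit"])

    comparisons = tuple(
        PairwiseComparison(
            group_i=sorted_labels[i],
            group_j=sorted_labels[j],
            mean_diff=float(abs(info["diff"])),
            q=float(info["q"]),
            span=info["span"],
            critical=float(info["crit"]),
            p=info["p"],
            significant=decisions[(i, j)],
        )
        for (i, j), info in sorted(raw.items())
    )
    return PosthocResult(
        comparisons=comparisons,
        alpha=alpha,
        mse=anova.mse,
        df_within=anova.df_within,
        n_harmonic=float(n_h),
    )


@dataclass
class SecondLevelReport:
    """ANOVA + post-hoc tables for each stimulus class of one contrast."""

    contrast: tuple[str, str]
    anova: dict[str, AnovaResult]  # keyed by stimulus class
    posthoc: dict[str, PosthocResult]
    samples: dict[str, list[ProbabilitySample]]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(ANOVA table, post-hoc table) as tidy data frames."""
        anova_rows = [
            {
                "stimulus_class": cls,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                **{f"mean_{g}": m for g, m in res.group_means.items()},
            }
            for cls, res in self.anova.items()
        ]
        posthoc_rows = [
            {
                "stimulus_class": cls,
                "group_i": c.group_i,
                "group_j": c.group_j,
                "mean_diff": c.mean_diff,
                "q": c.q,
                "span": c.span,
                "critical": c.critical,
                "p": c.p,
                "significant": c.significant,
            }
            for cls, res in self.posthoc.items()
            for c in res.comparisons
        ]
        return pd.DataFrame(anova_rows), pd.DataFrame(posthoc_rows)


def probability_samples(
    results: list[WithinGroupResult], stimulus_class: str
) -> list[ProbabilitySample]:
    """Per-group held-out probabilities for one stimulus class.

    Class-1 examples contribute ``p(class 1)``; class-2 examples
    contribute ``1 - p(class 1)`` so the value is always "probability of
    the example's own class".
    """
    samples = []
    for res in results:
        class1 = res.contrast[0]
        values = [
            pred.probability_class1
            if stimulus_class == class1
            else 1.0 - pred.probability_class1
            for pred in res.predictions
            if pred.condition == stimulus_class
        ]
        if not values:
            raise MissingDataError(
                f"group {res.group} has no predictions for {stimulus_class!r}"
            )
        samples.append(
            ProbabilitySample(
                group=res.group, stimulus_class=stimulus_class, values=np.array(values)
            )
        )
    return samples


def second_level_report(
    within_results: list[WithinGroupResult],
    alpha: float = 0.05,
    expected_groups: list[str] | None = None,
) -> SecondLevelReport:
    """ANOVA + Newman-Keuls on held-out probabilities, per stimulus class."""
    if not within_results:
        raise MissingDataError("no within-group results given")
    contrasts = {r.contrast for r in within_results}
    if len(contrasts) != 1:
        raise InvalidParameterError(f"results mix contrasts: {contrasts}")
    contrast = contrasts.pop()
    present = [r.group for r in within_results]
    if len(set(present)) != len(present):
        raise InvalidParameterError("duplicate group in within_results")
    if expected_groups is not None:
        missing = set(expected_groups) - set(present)
        if missing:
            raise MissingDataError(f"groups missing from results: {sorted(missing)}")

    anova, posthoc, samples = {}, {}, {}
    for stimulus_class in contrast:
        s = probability_samples(within_results, stimulus_class)
        samples[stimulus_class] = s
        anova[stimulus_class] = anova_oneway(s)
        posthoc[stimulus_class] = newman_keuls(s, alpha=alpha)
    return SecondLevelReport(
        contrast=contrast, anova=anova, posthoc=posthoc, samples=samples
    )
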