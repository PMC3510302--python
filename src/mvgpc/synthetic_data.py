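"""Synthetic event-related fMRI cohorts with controllable pattern structure.

Generates the three ingredients the analysis pipeline consumes:

* event schedules for a rapid event-related paradigm (three stimulus
  conditions, fixed trial counts, Poisson-spaced inter-stimulus
  intervals);
* per-subject condition "beta" volumes built as a group-level spatial
  pattern plus subject-level perturbation plus voxel noise, where the
  separability, support overlap, and subject variability of the
  condition patterns are the controllable knobs;
* optional BOLD time series consistent with the design matrix that
  :mod:`mvgpc.first_level` builds for the same schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mvgpc.errors import InvalidParameterError

#: Stimulus conditions, in canonical order.
CONDITIONS: tuple[str, ...] = ("neutral", "mild_happy", "intense_happy")

#: Seconds of rest appended after the last trial so the HRF tail is sampled.
SCHEDULE_TAIL = 16.0

#: Fraction of grid voxels used as the support of each condition pattern.
PATTERN_SUPPORT_FRACTION = 0.05

#: Per-group covariate defaults: (medication mean, medication sd, P(substance history)).
COVARIATE_DEFAULTS = {
    "HC": (0.0, 0.0, 0.0),
    "UD": (1.4, 1.1, 4.0 / 18.0),
    "BD": (2.5, 1.5, 5.0 / 16.0),
}


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    condition: str


@dataclass(frozen=True)
class EventSchedule:
    """Ordered, non-overlapping stimulus events for one run."""

    events: tuple[Event, ...]
    total_duration: float
    seed: int

    def __post_init__(self):
        onsets = self.onsets
        if np.any(np.diff(onsets) <= 0):
            raise InvalidParameterError("event onsets must be strictly increasing")
        ends = onsets[:-1] + self.durations[:-1]
        if np.any(onsets[1:] < ends - 1e-9):
            raise InvalidParameterError("events overlap")
        if self.events and onsets[-1] + self.durations[-1] > self.total_duration + 1e-9:
            raise InvalidParameterError("events extend past total_duration")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    @property
    def conditions(self) -> list[str]:
        return [e.condition for e in self.events]

    def interstimulus_intervals(self) -> np.ndarray:
        """Gaps between the end of each event and the next onset."""
        onsets, durations = self.onsets, self.durations
        return onsets[1:] - (onsets[:-1] + durations[:-1])

    def count(self, condition: str) -> int:
        return sum(1 for e in self.events if e.condition == condition)


@dataclass(frozen=True)
class GroupSpec:
    """Generative settings for one synthetic subject group.

    ``pattern_amplitude`` maps each condition to the per-voxel effect
    size of its spatial pattern (signal units, same scale as
    ``noise_sd``).  ``pattern_overlap`` is the fraction of support
    voxels shared between the condition patterns; ``subject_variability``
    is the standard deviation of the per-subject, per-condition pattern
    perturbation.
    """

    label: str
    n_subjects: int
    pattern_amplitude: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CONDITIONS}
    )
    pattern_overlap: float = 0.0
    subject_variability: float = 0.0
    noise_sd: float = 1.0
    medication_mean: float = 0.0
    medication_sd: float = 0.0
    substance_prob: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2")
        if not 0.0 <= self.pattern_overlap <= 1.0:
            raise InvalidParameterError("pattern_overlap must be in [0, 1]")
        if self.subject_variability < 0 or self.noise_sd < 0 or self.medication_sd < 0:
            raise InvalidParameterError("standard deviations must be >= 0")
        if not 0.0 <= self.substance_prob <= 1.0:
            raise InvalidParameterError("substance_prob must be in [0, 1]")
        missing = [c for c in CONDITIONS if c not in self.pattern_amplitude]
        if missing:
            raise InvalidParameterError(f"pattern_amplitude missing conditions: {missing}")

    @classmethod
    def for_label(cls, label: str, n_subjects: int = 18, **overrides) -> "GroupSpec":
        """Group spec with covariate distributions defaulted by label."""
        med_mean, med_sd, sub_p = COVARIATE_DEFAULTS.get(label, (0.0, 0.0, 0.0))
        kwargs = dict(
            medication_mean=med_mean, medication_sd=med_sd, substance_prob=sub_p
        )
        kwargs.update(overrides)
        return cls(label=label, n_subjects=n_subjects, **kwargs)


@dataclass
class SubjectRecord:
    """One subject's group membership, covariates, and condition volumes."""

    subject_id: str
    group: str
    medication_load: float
    substance_history: int
    betas: dict[str, np.ndarray]

    def __post_init__(self):
        missing = [c for c in CONDITIONS if c not in self.betas]
        if missing:
            raise InvalidParameterError(f"betas missing conditions: {missing}")
        shapes = {v.shape for v in self.betas.values()}
        if len(shapes) != 1:
            raise InvalidParameterError("beta volumes must share one shape")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.betas.values())).shape


def generate_paradigm(
    n_per_condition: int,
    stim_duration: float = 2.0,
    isi_mean: float = 4.9,
    seed: int = 0,
    isi_distribution: str = "poisson",
) -> EventSchedule:
    """Random event schedule: 3 conditions x ``n_per_condition`` trials.

    Condition order is a uniform random permutation.  Inter-stimulus
    intervals are drawn either as ``Poisson(10 * isi_mean) / 10`` (the
    default: a Poisson draw at 0.1 s granularity whose mean equals
    ``isi_mean``) or from an exponential distribution with the same
    mean (``isi_distribution="exponential"``).  ``total_duration`` is
    derived from the realized schedule plus a rest tail.
    """
    if n_per_condition < 1:
        raise InvalidParameterError("n_per_condition must be >= 1")
    if stim_duration <= 0 or isi_mean <= 0:
        raise InvalidParameterError("stim_duration and isi_mean must be > 0")
    if isi_distribution not in ("poisson", "exponential"):
        raise InvalidParameterError(f"unknown isi_distribution {isi_distribution!r}")

    rng = np.random.default_rng(seed)
    conditions = np.repeat(CONDITIONS, n_per_condition)
    rng.shuffle(conditions)
    n_events = conditions.size

    if isi_distribution == "poisson":
        isis = rng.poisson(isi_mean * 10.0, size=n_events - 1) / 10.0
    else:
        isis = rng.exponential(isi_mean, size=n_events - 1)

    onsets = np.zeros(n_events)
    # Poisson ISIs can be exactly 0; back-to-back events are allowed, but
    # onsets must still strictly increase, which stim_duration > 0 ensures.
    onsets[1:] = np.cumsum(isis + stim_duration)
    total = float(onsets[-1] + stim_duration + SCHEDULE_TAIL)
    events = tuple(
        Event(float(o), float(stim_duration), str(c)) for o, c in zip(onsets, conditions)
    )
    return EventSchedule(events=events, total_duration=total, seed=seed)


def _condition_patterns(
    spec: GroupSpec, grid_shape: tuple[int, ...], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Sparse condition patterns with a controlled shared support.

    Each condition's pattern has value ``pattern_amplitude[c]`` on a
    support of ``m`` voxels; a fraction ``pattern_overlap`` of the
    support is shared across all conditions, the rest is disjoint
    between conditions.
    """
    n_vox = int(np.prod(grid_shape))
    m = max(4, int(round(PATTERN_SUPPORT_FRACTION * n_vox)))
    n_shared = int(round(spec.pattern_overlap * m))
    n_unique = m - n_shared
    need = n_shared + n_unique * len(CONDITIONS)
    if need > n_vox:
        raise InvalidParameterError(
            f"grid too small for pattern supports ({need} > {n_vox} voxels)"
        )
    chosen = rng.choice(n_vox, size=need, replace=False)
    shared = chosen[:n_shared]
    patterns = {}
    for i, cond in enumerate(CONDITIONS):
        unique = chosen[n_shared + i * n_unique : n_shared + (i + 1) * n_unique]
        vol = np.zeros(n_vox)
        vol[shared] = spec.pattern_amplitude[cond]
        vol[unique] = spec.pattern_amplitude[cond]
        patterns[cond] = vol.reshape(grid_shape)
    return patterns


def generate_cohort(
    groups: list[GroupSpec],
    grid_shape: tuple[int, ...] = (12, 12, 12),
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate condition beta volumes and covariates for every subject.

    Each subject's beta volume for condition ``c`` is::

        group_pattern[c] + N(0, subject_variability) + N(0, noise_sd)

    with fresh perturbation and noise fields per subject and condition.
    Medication load is a zero-truncated normal; substance history is
    Bernoulli.  Deterministic for a fixed seed.
    """
    if not groups:
        raise InvalidParameterError("need at least one group spec")
    if len(grid_shape) != 3 or any(d < 4 for d in grid_shape):
        raise InvalidParameterError("grid_shape must be 3-D with all dims >= 4")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise InvalidParameterError("group labels must be unique")

    root = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    for spec in groups:
        grp_rng = np.random.default_rng(root.integers(2**63))
        patterns = _condition_patterns(spec, grid_shape, grp_rng)
        for i in range(spec.n_subjects):
            med = max(0.0, float(grp_rng.normal(spec.medication_mean, spec.medication_sd)))
            sub = int(grp_rng.random() < spec.substance_prob)
            betas = {}
            for cond in CONDITIONS:
                vol = patterns[cond].copy()
                if spec.subject_variability > 0:
                    vol += grp_rng.normal(0.0, spec.subject_variability, grid_shape)
                if spec.noise_sd > 0:
                    vol += grp_rng.normal(0.0, spec.noise_sd, grid_shape)
                betas[cond] = vol
            records.append(
                SubjectRecord(
                    subject_id=f"{spec.label}{i + 1:02d}",
                    group=spec.label,
                    medication_load=med,
                    substance_history=sub,
                    betas=betas,
                )
            )
    return records


def simulate_timeseries(
    subject: SubjectRecord,
    schedule: EventSchedule,
    tr: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_scans: int | None = None,
) -> np.ndarray:
    """BOLD time series consistent with the first-level design matrix.

    The signal is the sum over conditions of the subject's beta volume
    times the HRF-convolved condition regressor (the exact regressor
    :func:`mvgpc.first_level.build_design_matrix` produces for this
    schedule), plus white Gaussian noise.  Returns a 4-D array of shape
    ``grid_shape + (n_scans,)``.
    """
    from mvgpc.first_level import build_design_matrix

    if tr <= 0:
        raise InvalidParameterError("tr must be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    min_scans = math.ceil(schedule.total_duration / tr)
    if n_scans is None:
        n_scans = min_scans
    elif n_scans * tr < schedule.onsets[-1] + schedule.durations[-1]:
        raise InvalidParameterError(
            f"schedule ({schedule.total_duration:.1f}s) does not fit in "
            f"{n_scans} scans of {tr}s"
        )

    design = build_design_matrix(schedule, tr=tr, n_scans=n_scans)
    rng = np.random.default_rng(seed)
    grid = subject.grid_shape
    bold = np.zeros(grid + (n_scans,))
    for cond in CONDITIONS:
        regressor = design.column(cond)
        bold += subject.betas[cond][..., None] * regressor[None, None, None, :]
    if noise_sd > 0:
        bold += rng.normal(0.0, noise_sd, bold.shape)
    return bold
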