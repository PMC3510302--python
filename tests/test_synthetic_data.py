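import numpy as np
import pytest

from mvgpc.errors import InvalidParameterError
from mvgpc.synthetic_data import (
    CONDITIONS,
    GroupSpec,
    generate_cohort,
    generate_paradigm,
    simulate_timeseries,
)


class TestGenerateParadigm:
    def test_standard_schedule(self):
        sched = generate_paradigm(20, stim_duration=2.0, isi_mean=4.9, seed=1)
        assert len(sched.events) == 60
        for cond in CONDITIONS:
            assert sched.count(cond) == 20
        assert np.all(sched.interstimulus_intervals() >= 0)

    def test_minimal_schedule(self):
        sched = generate_paradigm(1, stim_duration=2.0, isi_mean=4.9, seed=0)
        assert len(sched.events) == 3
        assert np.all(np.diff(sched.onsets) > 0)

    def test_isi_sampler_mean(self):
        # Monte-Carlo check of the ISI sampler against its stated 4.9 s mean
        total, count = 0.0, 0
        for seed in range(10_000):
            isis = generate_paradigm(2, isi_mean=4.9, seed=seed).interstimulus_intervals()
            total += isis.sum()
            count += isis.size
        assert abs(total / count - 4.9) / 4.9 < 0.01

    def test_exponential_option_mean(self):
        isis = np.concatenate(
            [
                generate_paradigm(20, isi_mean=4.9, seed=s, isi_distribution="exponential"
                                  ).interstimulus_intervals()
                for s in range(200)
            ]
        )
        assert abs(isis.mean() - 4.9) / 4.9 < 0.05

    def test_deterministic_under_seed(self):
        a = generate_paradigm(20, seed=5)
        b = generate_paradigm(20, seed=5)
        assert a == b
        assert a != generate_paradigm(20, seed=6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_condition": 0},
            {"n_per_condition": 5, "stim_duration": 0.0},
            {"n_per_condition": 5, "isi_mean": -1.0},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_paradigm(**{"stim_duration": 2.0, "isi_mean": 4.9, "seed": 0, **kwargs})

    def test_events_fit_total_duration(self):
        sched = generate_paradigm(20, seed=3)
        assert sched.onsets[-1] + sched.durations[-1] <= sched.total_duration


class TestGroupSpec:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            GroupSpec(label="X", n_subjects=1)
        with pytest.raises(InvalidParameterError):
            GroupSpec(label="X", n_subjects=3, pattern_overlap=1.5)
        with pytest.raises(InvalidParameterError):
            GroupSpec(label="X", n_subjects=3, noise_sd=-0.1)

    def test_covariate_defaults_by_label(self):
        assert GroupSpec.for_label("UD").medication_mean == 1.4
        assert GroupSpec.for_label("BD").medication_mean == 2.5
        assert GroupSpec.for_label("HC").medication_mean == 0.0


class TestGenerateCohort:
    def test_null_cohort_is_pure_noise(self):
        spec = GroupSpec(label="G", n_subjects=10, noise_sd=1.0)
        recs = generate_cohort([spec], grid_shape=(6, 6, 6), seed=0)
        stack = np.stack([r.betas[c] for r in recs for c in CONDITIONS])
        assert abs(stack.mean()) < 0.05
        assert abs(stack.std() - 1.0) < 0.05

    def test_noiseless_disjoint_patterns(self):
        spec = GroupSpec(
            label="G",
            n_subjects=3,
            pattern_amplitude={c: 1.0 for c in CONDITIONS},
            pattern_overlap=0.0,
            subject_variability=0.0,
            noise_sd=0.0,
        )
        recs = generate_cohort([spec], grid_shape=(8, 8, 8), seed=0)
        first = recs[0]
        for rec in recs[1:]:
            for cond in CONDITIONS:
                np.testing.assert_array_equal(rec.betas[cond], first.betas[cond])
        dot = float(
            first.betas["intense_happy"].ravel() @ first.betas["neutral"].ravel()
        )
        assert dot == 0.0

    def test_amplitude_orders_contrast_magnitude(self):
        # sample-mean oracle over 50 simulated subjects per group
        def mean_contrast(amp, seed):
            spec = GroupSpec(
                label="G",
                n_subjects=50,
                pattern_amplitude={
                    "neutral": 0.0, "mild_happy": 0.0, "intense_happy": amp
                },
                noise_sd=1.0,
            )
            recs = generate_cohort([spec], grid_shape=(6, 6, 6), seed=seed)
            diffs = [
                np.abs(r.betas["intense_happy"] - r.betas["neutral"]).mean()
                for r in recs
            ]
            return np.mean(diffs)

        assert mean_contrast(1.0, seed=1) > mean_contrast(0.2, seed=1)

    def test_overlap_monotonicity(self):
        # expected distance between condition means cannot grow with overlap
        def mean_distance(overlap):
            spec = GroupSpec(
                label="G",
                n_subjects=2,
                pattern_amplitude={c: 1.0 for c in CONDITIONS},
                pattern_overlap=overlap,
                noise_sd=0.0,
            )
            recs = generate_cohort([spec], grid_shape=(8, 8, 8), seed=0)
            d = recs[0].betas["intense_happy"] - recs[0].betas["neutral"]
            return float(np.linalg.norm(d))

        distances = [mean_distance(f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(distances, distances[1:]))
        assert distances[-1] == 0.0

    def test_deterministic_under_seed(self):
        spec = GroupSpec(label="G", n_subjects=3, noise_sd=1.0)
        a = generate_cohort([spec], grid_shape=(6, 6, 6), seed=9)
        b = generate_cohort([spec], grid_shape=(6, 6, 6), seed=9)
        for ra, rb in zip(a, b):
            assert ra.medication_load == rb.medication_load
            for cond in CONDITIONS:
                np.testing.assert_array_equal(ra.betas[cond], rb.betas[cond])

    def test_empty_group_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_cohort([], grid_shape=(6, 6, 6), seed=0)

    def test_small_grid_rejected(self):
        spec = GroupSpec(label="G", n_subjects=2)
        with pytest.raises(InvalidParameterError):
            generate_cohort([spec], grid_shape=(3, 6, 6), seed=0)


@pytest.fixture(scope="module")
def small_schedule():
    return generate_paradigm(4, seed=2)


@pytest.fixture(scope="module")
def subject():
    spec = GroupSpec(
        label="G",
        n_subjects=2,
        pattern_amplitude={c: 1.0 for c in CONDITIONS},
        noise_sd=0.0,
    )
    return generate_cohort([spec], grid_shape=(4, 4, 4), seed=0)[0]


class TestSimulateTimeseries:
    def test_noiseless_round_trip(self, subject, small_schedule):
        from mvgpc.first_level import build_design_matrix, fit_glm

        bold = simulate_timeseries(subject, small_schedule, tr=2.0, noise_sd=0.0, seed=0)
        design = build_design_matrix(small_schedule, tr=2.0, n_scans=bold.shape[-1])
        recovered = fit_glm(bold, design)
        for cond in CONDITIONS:
            np.testing.assert_allclose(recovered[cond], subject.betas[cond], atol=1e-8)

    def test_pure_noise_statistics(self, small_schedule):
        from mvgpc.synthetic_data import SubjectRecord

        zero = SubjectRecord(
            subject_id="s", group="G", medication_load=0.0, substance_history=0,
            betas={c: np.zeros((5, 5, 5)) for c in CONDITIONS},
        )
        bold = simulate_timeseries(zero, small_schedule, tr=2.0, noise_sd=1.0, seed=1)
        assert abs(bold.mean()) < 0.02
        assert abs(bold.std() - 1.0) < 0.02

    def test_glm_estimates_unbiased(self, subject, small_schedule):
        # repeated-simulation oracle: mean estimation error ~ 0 across seeds
        from mvgpc.first_level import build_design_matrix, fit_glm

        errors = []
        design = None
        for seed in range(30):
            bold = simulate_timeseries(
                subject, small_schedule, tr=2.0, noise_sd=0.5, seed=seed
            )
            if design is None:
                design = build_design_matrix(small_schedule, tr=2.0, n_scans=bold.shape[-1])
            rec = fit_glm(bold, design)
            errors.append(
                np.mean([rec[c] - subject.betas[c] for c in CONDITIONS])
            )
        errors = np.asarray(errors)
        stderr = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) < 2 * stderr + 1e-12

    def test_schedule_too_long_rejected(self, subject, small_schedule):
        with pytest.raises(InvalidParameterError):
            simulate_timeseries(subject, small_schedule, tr=2.0, noise_sd=0.0, seed=0,
                                n_scans=3)
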