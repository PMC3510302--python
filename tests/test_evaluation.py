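import numpy as np
import pytest

from mvgpc.confounds import covariates_for
from mvgpc.errors import (
    InvalidParameterError,
    MissingDataError,
    PairingError,
)
from mvgpc.evaluation import (
    CvConfig,
    balanced_accuracy,
    bonferroni,
    lopo_between_group,
    loso_within_group,
    permutation_test,
)
from mvgpc.first_level import extract_features, variance_mask
from mvgpc.synthetic_data import CONDITIONS, GroupSpec, generate_cohort

FAST = CvConfig()


def _cohort_features(amplitudes=None, n_subjects=8, noise_sd=1.0, seed=0, label="G",
                     grid=(6, 6, 6), **spec_kwargs):
    amplitudes = amplitudes or {c: 0.0 for c in CONDITIONS}
    spec = GroupSpec(
        label=label, n_subjects=n_subjects, pattern_amplitude=amplitudes,
        noise_sd=noise_sd, **spec_kwargs,
    )
    recs = generate_cohort([spec], grid_shape=grid, seed=seed)
    mask = variance_mask(recs) if noise_sd > 0 else np.ones(grid, dtype=bool)
    return extract_features(recs, mask), recs


class TestBalancedAccuracy:
    # Table-2-style worked arithmetic
    @pytest.mark.parametrize(
        "tp,tn,expected",
        [(0.72, 0.50, 0.61), (1.0, 1.0, 1.0), (0.83, 0.67, 0.75)],
    )
    def test_worked_examples(self, tp, tn, expected):
        assert balanced_accuracy(tp, tn) == pytest.approx(expected)

    @pytest.mark.parametrize("tp,tn", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, tp, tn):
        with pytest.raises(InvalidParameterError):
            balanced_accuracy(tp, tn)


class TestLosoWithinGroup:
    def test_prediction_bookkeeping(self):
        feats, _ = _cohort_features(n_subjects=5, seed=1)
        res = loso_within_group(feats, ("intense_happy", "neutral"), config=FAST)
        assert len(res.predictions) == 10
        conds = [p.condition for p in res.predictions]
        assert conds.count("intense_happy") == 5
        assert conds.count("neutral") == 5
        # conservation identity
        assert res.accuracy == (res.tp_rate + res.tn_rate) / 2

    def test_separable_group_perfect_accuracy(self):
        feats, _ = _cohort_features(
            amplitudes={"neutral": 1.0, "mild_happy": 1.0, "intense_happy": 1.0},
            noise_sd=0.0, subject_variability=0.0, n_subjects=6,
        )
        res = loso_within_group(feats, ("intense_happy", "neutral"), config=FAST)
        assert res.accuracy == 1.0
        for p in res.predictions:
            expected_side = p.condition == "intense_happy"
            assert (p.probability_class1 > 0.5) == expected_side

    def test_null_group_near_chance(self):
        accs = [
            loso_within_group(
                _cohort_features(n_subjects=8, seed=s)[0],
                ("intense_happy", "neutral"),
                config=FAST,
            ).accuracy
            for s in range(5)
        ]
        assert 0.2 < np.mean(accs) < 0.8

    def test_missing_condition_rejected(self):
        feats, _ = _cohort_features(n_subjects=4)
        crippled = feats.subset(np.arange(feats.n_examples - 1))  # drop one example
        with pytest.raises(MissingDataError):
            loso_within_group(crippled, ("intense_happy", "neutral"), config=FAST)

    def test_no_subject_in_both_train_and_test(self):
        # structural leakage guard: every prediction's subject is absent
        # from its training fold by construction; fold indices partition
        # subjects one-to-one
        feats, _ = _cohort_features(n_subjects=6, seed=2)
        res = loso_within_group(feats, ("intense_happy", "neutral"), config=FAST)
        fold_subjects = {}
        for p in res.predictions:
            fold_subjects.setdefault(p.fold_index, set()).add(p.subject_id)
        assert len(fold_subjects) == 6
        for members in fold_subjects.values():
            assert len(members) == 1

    def test_relabeling_swaps_rates(self):
        feats, _ = _cohort_features(
            amplitudes={"neutral": 0.5, "mild_happy": 0.0, "intense_happy": 0.9},
            n_subjects=6, seed=3,
        )
        a = loso_within_group(feats, ("intense_happy", "neutral"), config=FAST)
        b = loso_within_group(feats, ("neutral", "intense_happy"), config=FAST)
        assert a.tp_rate == pytest.approx(b.tn_rate)
        assert a.tn_rate == pytest.approx(b.tp_rate)
        assert a.accuracy == pytest.approx(b.accuracy)

    def test_covariate_residualization_runs(self):
        import pandas as pd

        feats, recs = _cohort_features(n_subjects=6, seed=4)
        table = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in recs],
                "medication_load": np.linspace(0, 3, 6),
                "substance_history": [0, 1, 0, 1, 0, 1],
            }
        )
        cov = covariates_for(feats, table)
        for mode in ("train_only", "whole_sample"):
            res = loso_within_group(
                feats, ("intense_happy", "neutral"), covariates=cov,
                config=CvConfig(residualize_mode=mode),
            )
            assert 0.0 <= res.accuracy <= 1.0


class TestPermutationTest:
    def test_best_and_worst_case_p_values(self):
        calls = {"n": 0}

        def stat(labels):
            calls["n"] += 1
            return 1.0 if calls["n"] == 1 else 0.0  # observed beats all perms

        _, p = permutation_test(stat, np.array([1.0, -1.0]), lambda rng, y: -y, 99)
        assert p == pytest.approx(1 / 100)

        calls["n"] = 0

        def stat_worst(labels):
            calls["n"] += 1
            return 0.0 if calls["n"] == 1 else 1.0

        _, p = permutation_test(stat_worst, np.array([1.0, -1.0]), lambda rng, y: -y, 99)
        assert p == pytest.approx(1.0)

    def test_p_value_never_zero(self):
        _, p = permutation_test(
            lambda y: float(y[0]), np.array([1.0, -1.0]), lambda rng, y: -y, 50
        )
        assert p > 0.0

    def test_reproducible_under_seed(self):
        feats, _ = _cohort_features(n_subjects=5, seed=6)
        cfg = CvConfig(n_permutations=19, seed=3)
        a = loso_within_group(feats, ("intense_happy", "neutral"), config=cfg)
        b = loso_within_group(feats, ("intense_happy", "neutral"), config=cfg)
        assert a.p_value == b.p_value

    def test_significant_for_separable_data(self):
        feats, _ = _cohort_features(
            amplitudes={"neutral": 1.5, "mild_happy": 1.5, "intense_happy": 1.5},
            noise_sd=0.3, n_subjects=8, seed=7,
        )
        res = loso_within_group(
            feats, ("intense_happy", "neutral"),
            config=CvConfig(n_permutations=99, seed=0),
        )
        assert res.accuracy == 1.0
        assert res.p_value <= 0.05


class TestLopoBetweenGroup:
    def _two_groups(self, amp_a=0.0, amp_b=0.0, noise=1.0, n=6, seed=0, **kwargs):
        feats = []
        for label, amp, s in (("A", amp_a, seed), ("B", amp_b, seed + 1000)):
            fm, _ = _cohort_features(
                amplitudes={c: amp for c in CONDITIONS}, n_subjects=n,
                noise_sd=noise, seed=s, label=label, **kwargs,
            )
            feats.append(fm)
        return feats

    def test_fold_and_prediction_counts(self):
        fa, fb = self._two_groups(n=6)
        res = lopo_between_group(fa, fb, condition="intense_happy", config=FAST)
        assert len(res.predictions) == 12
        assert len({p.fold_index for p in res.predictions}) == 6
        assert res.accuracy == (res.sensitivity + res.specificity) / 2

    def test_disjoint_noiseless_groups_perfect(self):
        fa, fb = self._two_groups(
            amp_a=1.0, amp_b=2.0, noise=0.0, subject_variability=0.0, n=4,
        )
        res = lopo_between_group(fa, fb, condition="intense_happy", config=FAST)
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_identical_specs_near_chance(self):
        stats = []
        for s in range(5):
            fa, fb = self._two_groups(n=6, seed=100 + s)
            res = lopo_between_group(fa, fb, condition="neutral", config=FAST)
            stats.append((res.sensitivity + res.specificity) / 2)
        assert 0.2 < np.mean(stats) < 0.8

    def test_unequal_sizes_need_pairing(self):
        fa, fb = self._two_groups(n=6)
        fb_small = fb.subset(np.arange(fb.n_examples - 3))
        with pytest.raises(PairingError):
            lopo_between_group(fa, fb_small, condition="neutral", config=FAST)

    def test_bad_pairing_rejected(self):
        fa, fb = self._two_groups(n=4)
        pairing = [("A01", "B01"), ("A01", "B02"), ("A03", "B03"), ("A04", "B04")]
        with pytest.raises(PairingError):
            lopo_between_group(fa, fb, condition="neutral", pairing=pairing, config=FAST)

    def test_permutation_p_value(self):
        fa, fb = self._two_groups(
            amp_a=1.0, amp_b=2.0, noise=0.2, subject_variability=0.0, n=5,
        )
        res = lopo_between_group(
            fa, fb, condition="intense_happy",
            config=CvConfig(n_permutations=39, seed=1),
        )
        assert res.p_value <= 0.1


class TestBonferroni:
    def test_adjustment(self):
        assert bonferroni([0.01, 0.5]) == [0.02, 1.0]
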