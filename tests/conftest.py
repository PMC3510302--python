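import numpy as np
import pytest

from mvgpc.first_level import extract_features, variance_mask
from mvgpc.synthetic_data import GroupSpec, generate_cohort, generate_paradigm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def schedule():
    return generate_paradigm(n_per_condition=20, stim_duration=2.0, isi_mean=4.9, seed=1)


@pytest.fixture(scope="session")
def signal_cohort():
    """18 subjects, clear condition patterns, moderate noise."""
    spec = GroupSpec(
        label="HC",
        n_subjects=18,
        pattern_amplitude={"neutral": 0.8, "mild_happy": 1.0, "intense_happy": 1.2},
        noise_sd=0.5,
    )
    return generate_cohort([spec], grid_shape=(8, 8, 8), seed=7)


@pytest.fixture(scope="session")
def signal_features(signal_cohort):
    return extract_features(signal_cohort, variance_mask(signal_cohort))
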