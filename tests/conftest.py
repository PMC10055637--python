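import numpy as np
import pytest

import leapd


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects, 20-s recordings: quick fixture for training tests."""
    spec = leapd.SyntheticSpec(n_subjects=30, duration=20.0, seed=3)
    return leapd.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_ds(small_cohort):
    return small_cohort.to_dataset()


@pytest.fixture(scope="session")
def strong_ds():
    """The default strong-effect cohort: 120 subjects, 60-s recordings."""
    spec = leapd.SyntheticSpec(n_subjects=120, duration=60.0, seed=7)
    return leapd.generate_cohort(spec).to_dataset()


@pytest.fixture(scope="session")
def strong_cache(strong_ds):
    return leapd.FeatureCache(strong_ds, max_order=12)


@pytest.fixture(scope="session")
def strong_loocv(strong_ds, strong_cache):
    """LOOCV of the full pipeline on the strong-effect cohort."""
    return leapd.cross_validate(strong_ds, cache=strong_cache)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
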