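import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msiclf import SimConfig, assign_groups, compute_bin_spec, generate_cohort
from msiclf.featurize import dataset_extremes

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TINY_CONFIG = SimConfig(
    n_tmas=2,
    n_patients_both=8,
    spectra_per_core=(3, 5),
    axis_points=300,
    mz_min=800.0,
    mz_max=860.0,
    n_peaks=12,
    n_effect_peaks=3,
    fold_change=3.0,
    seed=42,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 2-TMA, 4-patient paired cohort small enough for every unit test."""
    return generate_cohort(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_groups(tiny_cohort):
    return assign_groups(tiny_cohort.spectra, tiny_cohort.annotations)


@pytest.fixture(scope="session")
def tiny_bin_spec(tiny_cohort):
    extremes = list(dataset_extremes(tiny_cohort.spectra).values())
    return compute_bin_spec(extremes, width=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
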