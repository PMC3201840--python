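import numpy as np
import pytest

from cgmcal import make_schedule, simulate_study


@pytest.fixture(scope="session")
def small_schedule():
    """A shortened study design (5 h, two calibrations) for fast MCMC tests."""
    return make_schedule(study_end=300.0, psi=(20.0, 160.0))


@pytest.fixture(scope="session")
def small_dataset(small_schedule):
    """Three individuals simulated from the reference population."""
    ds, truths = simulate_study(
        n_individuals=3,
        schedule=small_schedule,
        missing_rate=0.0,
        rng=np.random.default_rng(42),
    )
    return ds, truths


@pytest.fixture(scope="session")
def full_dataset():
    """A full-size simulated study (12 individuals, default schedule)."""
    ds, truths = simulate_study(missing_rate=0.01, rng=np.random.default_rng(7))
    return ds, truths
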