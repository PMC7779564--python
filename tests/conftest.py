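import numpy as np
import pytest

from coeruleus.phantom import DEFAULT_GRID, PhantomConfig
from coeruleus.volumes import GridSpec


@pytest.fixture(scope="session")
def default_grid() -> GridSpec:
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """A 10x10x10 grid at 0.5 mm with origin at zero, for hand examples."""
    return GridSpec((10, 10, 10), (0.5, 0.5, 0.5), (0.0, 0.0, 0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def quiet_config() -> PhantomConfig:
    """Noiseless, jitter-free phantom with flat profiles for closed-form checks."""
    from coeruleus.phantom import noiseless_config

    return noiseless_config(PhantomConfig(n_subjects=1, seed=7), flat_profiles=True)


@pytest.fixture(scope="session")
def small_cohort_report():
    """One shared 12-subject pipeline run for tests that need cohort outputs."""
    from coeruleus.pipeline import run_recovery_experiment

    return run_recovery_experiment(PhantomConfig(n_subjects=12, seed=11))
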