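import numpy as np
import pytest

from tdpe import (
    AcquisitionParams,
    CohortConfig,
    TDParams,
    generate_cohort,
    generate_schedule,
)


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(seed=1)


@pytest.fixture(scope="session")
def congruent_schedule():
    """Purely congruent sucrose trials: closed-form TD behaviour."""
    return generate_schedule(
        n_sucrose=12, n_nosol=0, n_saliva=0, p_violation=0.0,
        n_fixed_initial=12, seed=0,
    )


@pytest.fixture(scope="session")
def small_acq():
    """Short acquisition covering a small schedule."""
    return AcquisitionParams(tr_s=2.1, n_volumes=80)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = CohortConfig(seed=3)
    obs, truth = generate_cohort(cfg)
    return cfg, obs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
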