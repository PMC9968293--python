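import numpy as np
import pytest

from coreg.cohort import CohortConfig, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten participants at full per-condition trial counts; shared across
    endpoint/kernel tests (read-only)."""
    return simulate_cohort(CohortConfig(n_participants=10, trials_per_condition=160,
                                        seed=2024))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two participants, minimal trial counts: bookkeeping-level checks."""
    return simulate_cohort(CohortConfig(n_participants=2, trials_per_condition=20,
                                        seed=7))
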