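import numpy as np
import pytest

from oncoscore import CohortConfig, HazardConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,500-patient cohort shared by read-only tests."""
    config = CohortConfig(n_patients=1500, seed=42)
    return generate_cohort(config, HazardConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
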