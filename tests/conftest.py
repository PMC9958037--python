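import numpy as np
import pytest

from veinflow.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Rendered default cohort (26 reflux + 15 control limbs), fixed seed."""
    return generate_cohort(CohortConfig(), seed=7)


@pytest.fixture(scope="session")
def truth_cohort():
    """Ground-truth-only default cohort (no rendered cines)."""
    return generate_cohort(CohortConfig(), seed=11, render=False)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free rendered cohort for oracle-equivalence checks."""
    return generate_cohort(CohortConfig(noise_sd=0.0), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
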