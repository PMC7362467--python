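import numpy as np
import pytest

from rheumqc.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def commercial_cohort():
    """Default 28-sample cohort with simulated DL curves (shared, read-only)."""
    return generate_cohort(CohortSpec.commercial_default(seed=1))


@pytest.fixture(scope="session")
def commercial_cohort_nocurves():
    return generate_cohort(CohortSpec.commercial_default(seed=1), simulate_curves=False)
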