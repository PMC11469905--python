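import numpy as np
import pytest

from nephromet import CohortConfig, ThresholdConfig, generate_cohort


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-structure cohort (16 kidneys, 288 slides), generated once."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
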