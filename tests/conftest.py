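import numpy as np
import pytest

from pairedomics.io import load_reference_catalog
from pairedomics.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference_catalog():
    return load_reference_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort shared across tests."""
    cfg = CohortConfig(n_patients=4, relapse_fraction=0.5, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
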