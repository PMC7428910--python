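import numpy as np
import pytest

from elmh import SimulationConfig, fit_rasch, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-condition cohort (352 persons, mixed aberrant) shared
    across test modules."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    return fit_rasch(default_cohort.to_numpy(), 1, 5)


@pytest.fixture(scope="session")
def conforming_cohort():
    """Aberrant-free cohort with mild noise, for recovery-style checks."""
    return simulate_cohort(
        SimulationConfig(n_persons=400, aberrant_fraction=0.0,
                         noise_sd=0.3, seed=21))
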