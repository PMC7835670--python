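import numpy as np
import pytest

from splicescreen.simulate import (
    SimulationConfig,
    generate_reference,
    simulate_junction_counts,
    standard_cohort,
)


@pytest.fixture(scope="session")
def cohort_config() -> SimulationConfig:
    """A small standard cohort with all eight planted-event flavours."""
    return standard_cohort(seed=7, n_genes=12)


@pytest.fixture(scope="session")
def bundle(cohort_config):
    return generate_reference(cohort_config)


@pytest.fixture(scope="session")
def cohort(cohort_config, bundle):
    counts, samples = simulate_junction_counts(cohort_config, bundle)
    return counts, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
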