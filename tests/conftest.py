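import warnings

import pytest

from clonedyn import CohortConfig, generate_longitudinal_cohort

# statsmodels emits ConvergenceWarnings on near-boundary variance components;
# the package converts the ones that matter into its own error types
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_world_config() -> CohortConfig:
    """Default longitudinal world: 40 individuals, visits 0/2/10/15/20 y,
    retention 40/38/40/38/24, dual replicates at ~3891x."""
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def longitudinal_cohort(default_world_config):
    return generate_longitudinal_cohort(default_world_config)


@pytest.fixture(scope="session")
def growth_cohort_config() -> CohortConfig:
    """35-individual cohort with probabilistic study-schedule dropout, used by
    the growth-recovery tests."""
    return CohortConfig(
        seed=5, n_individuals=35, dropout_pattern=(1.0, 0.95, 1.0, 0.95, 0.6)
    )
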