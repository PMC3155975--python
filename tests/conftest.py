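import numpy as np
import pandas as pd
import pytest

from cpcei.cohort_io import ExpressionCohort
from cpcei.synthetic_cohorts import SimulationConfig, simulate_cohort_family


def make_cohort(values: np.ndarray, cohort_id: str = "C") -> ExpressionCohort:
    p, n = values.shape
    return ExpressionCohort(
        cohort_id,
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(p)],
            columns=[f"s{j}" for j in range(n)],
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_family():
    """One simulated 3-cohort family, small enough for fast unit tests."""
    cfg = SimulationConfig(
        n_cohorts=3, n_genes=400, n_samples=50, genes_per_factor=25,
        n_variable_background=50,
    )
    return simulate_cohort_family(cfg, seed=7)


@pytest.fixture(scope="session")
def default_family():
    """A family at the default study conditions (5 cohorts x 80 samples)."""
    return simulate_cohort_family(seed=11)
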