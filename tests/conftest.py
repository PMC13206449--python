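import numpy as np
import pandas as pd
import pytest

from tivbench import SimulationConfig, simulate_cohort, simulate_measures

SEED = 7


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_per_sex=300, seed=SEED, n_units=12)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_cohort):
    matrix, truth = simulate_measures(small_cohort, small_config)
    return small_cohort, matrix, truth


def toy_cohort(rows):
    """Build a cohort frame from (id, sex, age_months, tiv) tuples."""
    df = pd.DataFrame(rows, columns=["participant_id", "sex", "age_months", "tiv"])
    return df.set_index("participant_id")
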