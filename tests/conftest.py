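import numpy as np
import pandas as pd
import pytest

from stuntsem.cohort import generate_cohort
from stuntsem.config import GeneratorConfig
from stuntsem.taxa import generate_taxa_counts


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_children=120, seed=42, n_taxa=80, n_families=10, depth_mean=5000)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_cohort(small_config)
    return cohort, truth


@pytest.fixture(scope="session")
def small_taxa(small_config, small_cohort):
    _, truth = small_cohort
    return generate_taxa_counts(small_config, truth)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[2, 2, 4, 0], [1, 2, 3, 4], [10, 0, 0, 0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
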