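import numpy as np
import pandas as pd
import pytest

from poolgwas import SimulationConfig, load_genotype_counts

# Combined-cohort genotype counts (test + replication) for the two
# individually genotyped SNPs, as (case triple, control triple).
RS11845632_COMBINED = ((46, 195, 168), (94, 262, 159))
RS2196447_COMBINED = ((67, 220, 122), (57, 245, 213))


@pytest.fixture(scope="session")
def count_table() -> pd.DataFrame:
    return load_genotype_counts()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture()
def small_config() -> SimulationConfig:
    """A fast, small study: 40 SNPs, 4 pools of 25-35, triplicates."""
    return SimulationConfig(
        n_cases_female=30, n_cases_male=25,
        n_controls_female=35, n_controls_male=28,
        n_snps=40, n_effect_snps=8, seed=7,
    )
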