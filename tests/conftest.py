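import numpy as np
import pandas as pd
import pytest

from hetspan import synthetic_data as sd


@pytest.fixture(scope="session")
def null_pair():
    """Small two-cohort panel with no heterozygote excess (both f = 0)."""
    cfg = sd.SimConfig(n_per_cohort=200, n_snps=1500, seed=11)
    return sd.simulate_cohort_pair(cfg)


@pytest.fixture(scope="session")
def excess_pair():
    """Cohort B carries heterozygote excess at common SNPs only."""
    cfg = sd.SimConfig(
        n_per_cohort=300, n_snps=3000,
        f_cohort={"A": 0.0, "B": [sd.FRule(f=-0.05, maf_min=0.25)]},
        seed=7)
    return sd.simulate_cohort_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
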