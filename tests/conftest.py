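"""Shared fixtures: small simulated panels and cohorts, toy summary statistics."""

import numpy as np
import pandas as pd
import pytest

from refpgs.config import SimConfig
from refpgs import synthdata


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_samples=1500, n_snps=220, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synthdata.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    cohort = synthdata.simulate_phenotypes(small_panel, small_config)
    cohort = synthdata.simulate_aosw(cohort, small_config)
    return synthdata.assign_families(cohort, small_config)


def make_sumstats(
    betas,
    ses=None,
    chromosomes=None,
    n=10000,
    effect_allele="A",
    other_allele="G",
    prefix="v",
):
    """Build a valid SumStats frame from effect sizes (p from the normal z)."""
    from scipy import stats

    betas = np.asarray(betas, float)
    m = len(betas)
    ses = np.full(m, 0.01) if ses is None else np.asarray(ses, float)
    chromosomes = np.ones(m, int) if chromosomes is None else np.asarray(chromosomes, int)
    z = np.abs(betas / ses)
    p = np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}{i}" for i in range(m)],
            "chromosome": chromosomes,
            "position": np.arange(m) + 1,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "beta": betas,
            "standard_error": ses,
            "p_value": p,
            "n": n,
            "effect_allele_frequency": 0.5,
        }
    )


@pytest.fixture
def sumstats_factory():
    return make_sumstats
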