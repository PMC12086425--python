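"""Shared fixtures: small synthetic panels, GWAS pairs and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import crosstrait as ct
from crosstrait.sumstats import InstrumentSet


@pytest.fixture(scope="session")
def small_arch():
    return ct.ArchitectureConfig(n_blocks=40, block_size=25, n1=40_000,
                                 n2=40_000, n_overlap=0, rho_e=0.0, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_arch):
    return ct.make_ld_panel(small_arch)


@pytest.fixture(scope="session")
def small_gwas_pair(small_arch, small_panel):
    return ct.simulate_sumstats(small_arch, small_panel)


@pytest.fixture(scope="session")
def linear_cohort():
    cfg = ct.CohortConfig(
        n=10_000, causal_fn=ct.CausalFunction("linear", slope=0.1), seed=3)
    return ct.simulate_cohort(cfg)


def instrument_set(d, n_x: int = 50_000, n_y: int = 50_000) -> InstrumentSet:
    """Wrap a simulate_instrument_betas draw as a harmonized InstrumentSet."""
    n = len(d["beta_x"])
    df = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(n)],
            "chr": 1,
            "pos": np.arange(n) * 10_000 + 1,
            "ea": "A", "oa": "G", "eaf_x": 0.5, "eaf_y": 0.5,
            "beta_x": d["beta_x"], "se_x": d["se_x"],
            "beta_y": d["beta_y"], "se_y": d["se_y"],
            "n_x": n_x, "n_y": n_y,
            "palindromic": False, "flipped": False,
        }
    )
    return InstrumentSet(df=df)


@pytest.fixture
def make_instruments():
    return instrument_set
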