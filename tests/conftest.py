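import numpy as np
import pandas as pd
import pytest

from panprog import ExpressionMatrix, SimConfig, simulate_pan_cancer
from panprog.datatypes import clinical_table


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down pan-cancer study for fast integration tests."""
    return SimConfig(n_cancers=2, samples_per_cancer=150, n_mirna=60, n_lncrna=80, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_pan_cancer(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_matrix(values, features=None, samples=None, omic="miRNA", scale="log2p1"):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), omic, scale)


def make_clinical(os_days, samples=None, **kw):
    samples = samples or [f"s{i}" for i in range(len(os_days))]
    return clinical_table(samples, os_days, **kw)
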