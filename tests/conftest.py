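import numpy as np
import pandas as pd
import pytest

from annotawas.annotation import CategoryCensus, CategoryScheme
from annotawas.sim import SimConfig, simulate_study


AB = CategoryScheme("AB", ("A", "B"))


def make_census(counts: dict) -> CategoryCensus:
    scheme = CategoryScheme("/".join(counts), tuple(counts))
    return CategoryCensus(scheme, pd.Series(counts))


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by read-only tests."""
    config = SimConfig(
        n_samples=500, n_variants=2000, n_chromosomes=2, n_causal=4,
        heritability=0.5, seed=20260901,
    )
    return config, simulate_study(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
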