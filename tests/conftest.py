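import numpy as np
import pandas as pd
import pytest

from myoqtl.sim import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study reused by read-only tests."""
    cfg = SimConfig(
        n_samples=120,
        n_genes=150,
        n_variants=3000,
        frac_ase_sites=0.05,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
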