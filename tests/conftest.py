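import numpy as np
import pytest

import osteosig as og


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale simulated cohort shared by read-only tests."""
    cfg = og.SimConfig(
        n_samples=60, n_genes=400, immune_module_size=120,
        biclusters=((20, 15, 2.0), (15, 12, 2.0)), rng_seed=7,
    )
    counts, clinical, truth = og.simulate_cohort(cfg)
    return cfg, counts, clinical, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
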