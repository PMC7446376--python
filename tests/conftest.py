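import numpy as np
import pytest

from bcmarkers import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample cohort with a compact transcriptome, shared across tests."""
    cfg = SimConfig(n_samples=300, n_genes=150, block_size=10, seed=11)
    truth, expr, panel, clin = generate_cohort(cfg)
    return cfg, truth, expr, panel, clin


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
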