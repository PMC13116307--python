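import numpy as np
import pytest

from nbprs import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = sd.SyntheticConfig(
        n_samples=500, n_blocks=12, snps_per_block=5, n_genes=120,
        modules={"M14": 30, "M2": 20}, seed=42,
    )
    return cfg, sd.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
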