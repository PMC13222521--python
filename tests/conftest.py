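import numpy as np
import pytest

from clcnet import SimConfig, simulate_dataset, standard_config


@pytest.fixture(scope="session")
def standard_fixture():
    """The canonical dataset: n=600, m=4000, 5 chromosomes, h²=0.7, seed 7."""
    return simulate_dataset(standard_config())


@pytest.fixture(scope="session")
def small_fixture():
    """Fast dataset for unit tests: n=150, m=300, 3 chromosomes."""
    cfg = SimConfig(n_samples=150, n_snps=300, n_chromosomes=3, n_causal=8,
                    chrom_length_bp=2_000_000, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
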