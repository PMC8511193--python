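import numpy as np
import pytest

from ldff.simdata import simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """20 haplotypes x 200 sites on one 10 Mb chromosome."""
    return simulate_panel(20, 200, 1, switch_rate=0.02, mutation_rate=0.01,
                          seed=101, chrom_length_bp=10_000_000)


@pytest.fixture(scope="session")
def toy_panel():
    """40 haplotypes x (2 chromosomes x 1000 sites) on 50 Mb chromosomes."""
    return simulate_panel(40, 1000, 2, switch_rate=0.02, mutation_rate=0.01,
                          seed=11, chrom_length_bp=50_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
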