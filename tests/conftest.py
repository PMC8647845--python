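import numpy as np
import pytest

from centel.simgenome import SimConfig, simulate_genome, simulate_hic, simulate_ltr_loci


@pytest.fixture(scope="session")
def small_config():
    """3 chromosomes x 3 Mb at 100-kb bins: every stage runs in seconds."""
    return SimConfig(chrom_lengths=(3_000_000,) * 3, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_hic(small_config, small_genome):
    model, _ = small_genome
    return simulate_hic(model, small_config)


@pytest.fixture(scope="session")
def demo_loci():
    from centel.simgenome import DEMO_FAMILY_MIX

    cfg = SimConfig(seed=21, n_ltr_loci=60, ltr_family_mix=DEMO_FAMILY_MIX)
    return simulate_ltr_loci(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
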