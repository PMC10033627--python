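import numpy as np
import pytest

from unihaced.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy tank simulation shared across tests (3 species)."""
    cfg = SimConfig(
        seed=11,
        n_species=3,
        haplotypes_per_species=2,
        molecules_per_haplotype=2,
        first_pcr_cycles=3,
        umi_chimera_fraction=0.05,
        reads_per_umi_range=(20, 60),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-error, zero-chimera simulation (2 species)."""
    cfg = SimConfig(
        seed=5,
        n_species=2,
        haplotypes_per_species=2,
        molecules_per_haplotype=1,
        first_pcr_cycles=2,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        umi_chimera_fraction=0.0,
        reads_per_umi_range=(5, 10),
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
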