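import numpy as np
import pytest

from altadapt.popgen import HaplotypeSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_hapset(rng):
    """20 haplotypes x 12 sites, two populations, random alleles."""
    alleles = rng.integers(0, 2, size=(20, 12)).astype(np.int8)
    positions = np.sort(rng.choice(50_000, size=12, replace=False))
    pops = np.array(["TIB"] * 10 + ["HAN"] * 10)
    return HaplotypeSet(alleles=alleles, positions=positions,
                        chromosome="1", populations=pops)


@pytest.fixture(scope="session")
def default_sim():
    """One default sweep simulation shared across tests (read-only)."""
    from altadapt.simdata import SimulationConfig, simulate_split_populations
    return simulate_split_populations(SimulationConfig(seed=11))
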