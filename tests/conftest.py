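import numpy as np
import pytest

from crossmut.simulate import GenomeIndex, SimSpeciesConfig, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """20 kb synthetic genome shared across tests."""
    seq, freq = simulate_genome(20_000, 0.42, seed=123)
    return seq, freq


@pytest.fixture(scope="session")
def genome_index(small_genome):
    seq, _ = small_genome
    return GenomeIndex(seq)


@pytest.fixture
def base_config():
    return SimSpeciesConfig(
        species_name="mouse",
        genome_length=20_000,
        callable_bases=10_000_000,
        control_rate_per_mb=1.0,
        treated_rate_per_mb=3.0,
        germline_density_per_mb=0.0,
    )
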