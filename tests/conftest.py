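import numpy as np
import pytest

from oriscan import generate_genome, scan_genome
from oriscan.simulate import SyntheticSpec


@pytest.fixture(scope="session")
def planted_sim():
    """The reference planted-motif study: 10-Mb genome, 500 in-threshold
    cassettes, seed 1. Shared across recovery tests (generation ~seconds)."""
    spec = SyntheticSpec(seed=1)  # defaults: 10 Mb, 500 origins
    genome, truth = generate_genome(spec)
    return spec, genome, truth


@pytest.fixture(scope="session")
def planted_scan(planted_sim):
    _, genome, _ = planted_sim
    return scan_genome(genome)


@pytest.fixture(scope="session")
def decoy_sim():
    """The decoy-cassette study for the ML layer: 2-Mb genome with origin
    cassettes and twice as many composition-matched, CpG-poor decoys."""
    spec = SyntheticSpec(
        genome_length=2_000_000, n_origins=150, n_decoys=300, seed=1
    )
    genome, truth = generate_genome(spec)
    return spec, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
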