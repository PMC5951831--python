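import numpy as np
import pytest

from deaminoscan import (
    ReferenceSequence,
    SimulationConfig,
    build_context_index,
    simulate_reference,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11, contig_length=50_000, gc_content=0.45)


@pytest.fixture(scope="session")
def reference(sim_config):
    """A 50 kb seeded random contig shared across tests."""
    return simulate_reference(sim_config)


@pytest.fixture(scope="session")
def context_index(reference):
    return build_context_index(reference)


@pytest.fixture
def tiny_reference():
    """A hand-written contig where every context can be read off by eye."""
    return ReferenceSequence({"chr1": "ACGTACGTACGTACGTACGT", "chr2": "TTTTCGTTTT"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
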