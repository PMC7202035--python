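import numpy as np
import pytest

from mapscaff import simulate
from mapscaff.assembly_model import AssemblySeq


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_genome():
    """Two 150 kb chromosomes, fixed seed, shared across tests."""
    return simulate.simulate_genome(2, [150_000, 150_000], gc=0.44, seed=42)


@pytest.fixture(scope="session")
def small_map(small_genome):
    markers, truth = simulate.simulate_map(small_genome, markers_per_mb=300,
                                           seed=42)
    return markers, truth


@pytest.fixture(scope="session")
def fragmented(small_genome):
    """Clean fragmentation (no injected misassemblies) of small_genome."""
    return simulate.fragment_assembly(small_genome, mean_scaffold_len=30_000,
                                      seed=42)
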