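import numpy as np
import pytest

from mitoforge import simulate


@pytest.fixture(scope="session")
def small_genome() -> str:
    """Repeat-free 2 kb circular test genome."""
    return simulate.simulate_genome(length=2000, gc_fraction=0.44, seed=42)


@pytest.fixture(scope="session")
def mito_genome() -> str:
    """Full-size (16,563 bp) repeat-free circular test genome."""
    return simulate.simulate_genome(length=16_563, gc_fraction=0.44, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
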