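import numpy as np
import pytest

from hupmap.genome_io import GenomeContext, Peak


@pytest.fixture
def genome() -> GenomeContext:
    """A ~7 Mbp circular chromosome with oriC at 0 and ter opposite."""
    return GenomeContext("chr_sim", 7_000_000)


@pytest.fixture
def small_genome() -> GenomeContext:
    return GenomeContext("mini", 10_000)


def make_peak(start: int, end: int, fold: float | None = None,
              rep: str = "", name: str = "") -> Peak:
    return Peak("chr_sim", start, end, fold, rep, name)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
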