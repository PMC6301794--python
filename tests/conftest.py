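import numpy as np
import pytest

from macrospace import introgression_sim as isim


@pytest.fixture(scope="session")
def small_map():
    """A light genome for simulation tests: one big autosome, a small X."""
    return isim.ChromosomeMap(
        (
            isim.Chromosome("2", 47_000_000, 1.1),
            isim.Chromosome("X", 1_000_000, 0.05, kind="X"),
            isim.Chromosome("mito", 19_000, 0.0, kind="mito"),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
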