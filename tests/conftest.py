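import numpy as np
import pytest

from vgwas_sim import generate_hwe


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_diploid():
    """500 diploid samples x 40 loci, MAFs spread over (0.05, 0.5)."""
    mafs = np.linspace(0.05, 0.5, 40)
    return generate_hwe(500, mafs, ploidy=2, seed=101)


@pytest.fixture
def small_haploid():
    mafs = np.linspace(0.05, 0.5, 40)
    return generate_hwe(500, mafs, ploidy=1, seed=102)
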