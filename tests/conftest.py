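import numpy as np
import pytest

from riailmap import generate_marker_map, simulate_riail_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """120 lines x 60 markers (3 chromosomes), for fast unit tests."""
    mmap = generate_marker_map(3, 20, chrom_length_cm=50.0)
    return simulate_riail_genotypes(mmap, 120, map_expansion=4.0, seed=11)


@pytest.fixture(scope="session")
def riail_panel():
    """Study-scale panel: 300 lines x 600 markers on 6 chromosomes."""
    mmap = generate_marker_map(6, 100, chrom_length_cm=50.0)
    return simulate_riail_genotypes(mmap, 300, map_expansion=4.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
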