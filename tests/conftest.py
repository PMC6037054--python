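import numpy as np
import pytest

from dropletquant import ImageSimParams, simulate_stack


def make_dumbbell(amp=10000, sig=13.0, sep=32, size=121, bg=100):
    """Two overlapping Gaussian spots whose top quantization level is a
    single connected ~900 px blob; the recursion must split it in two."""
    rr, cc = np.mgrid[0:size, 0:size]
    c = size // 2
    g1 = np.exp(-((rr - c) ** 2 + (cc - (c - sep // 2)) ** 2) / (2 * sig**2))
    g2 = np.exp(-((rr - c) ** 2 + (cc - (c + sep // 2)) ** 2) / (2 * sig**2))
    return np.round(bg + amp * (g1 + g2)).astype(np.uint16)


@pytest.fixture(scope="session")
def dumbbell_plane():
    return make_dumbbell()


@pytest.fixture(scope="session")
def small_stack():
    """A small synthetic scene shared by I/O and pipeline tests."""
    params = ImageSimParams(height=256, width=256, n_cells=4,
                            droplets_per_cell=("fixed", 1), seed=7)
    return simulate_stack(params)
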