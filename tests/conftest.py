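import numpy as np
import pytest

from qpat.grids import VoxelGrid
from qpat.spectra import make_synthetic_spectra


@pytest.fixture(scope="session")
def spectra():
    return make_synthetic_spectra()


@pytest.fixture(scope="session")
def wavelengths():
    return [688.0, 721.0, 765.0, 811.0, 867.0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return VoxelGrid(np.zeros((8, 8, 8)), pitch=0.25, origin=(0.0, 0.0, 0.125))
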