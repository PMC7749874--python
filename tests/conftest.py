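import numpy as np
import pytest

from oemdose.beam import generate_spectrum
from oemdose.materials import default_materials
from oemdose.phantoms import make_pmma_cylinder, make_pregnant_phantom
from oemdose.transport import default_spectrum


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def spectrum80():
    """80 kV spectrum calibrated to the 4.76 mm Al half-value layer."""
    return default_spectrum(80.0)


@pytest.fixture(scope="session")
def spectrum100():
    return default_spectrum(100.0)


@pytest.fixture(scope="session")
def raw_spectrum80():
    """Uncalibrated 80 kV spectrum with a nominal 3 mm Al filtration."""
    return generate_spectrum(80.0, 3.0)


@pytest.fixture(scope="session")
def cylinder():
    return make_pmma_cylinder(voxel_size_mm=8.0, length_mm=200.0)


@pytest.fixture(scope="session")
def pregnant():
    return make_pregnant_phantom(voxel_size_mm=5.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
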