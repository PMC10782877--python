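import numpy as np
import pytest

from wirdrs.errors import ErrorConfig
from wirdrs.forward import (
    default_chromophore,
    default_standard,
    generate_grid_dataset,
)
from wirdrs.spectra import ProbeGeometry, Spectrum, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry(1)


@pytest.fixture(scope="session")
def chromo(grid):
    return default_chromophore(grid)


@pytest.fixture(scope="session")
def standard(grid):
    return default_standard(grid)


@pytest.fixture(scope="session")
def error_config():
    return ErrorConfig()


@pytest.fixture(scope="session")
def mini_dataset(grid):
    """5x5 label grid: 25 perfect spectra on the default wavelength grid."""
    return generate_grid_dataset(5, 5, grid=grid)


@pytest.fixture(scope="session")
def dataset_1520(grid):
    """The canonical 40x38 label grid (1520 perfect spectra)."""
    return generate_grid_dataset(grid=grid)


@pytest.fixture
def gaussian_spectrum(grid):
    """Smooth single-peak fixture well inside the band."""
    lam = grid.wavelengths_nm
    return Spectrum(grid, 0.05 + np.exp(-(((lam - 530.0) / 18.0) ** 2)), "gray")
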