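import numpy as np
import pytest

from cytosers.materials import SILVER, OpticalConstants, permittivity


@pytest.fixture(scope="session")
def eps_ag_532():
    """Silver permittivity at the 532 nm excitation wavelength."""
    return permittivity(SILVER, 532.0)


@pytest.fixture(scope="session")
def optics_silver():
    """Vacuum ambient over a silver substrate at 532 nm."""
    return OpticalConstants(wavelength=532.0)


@pytest.fixture(scope="session")
def optics_matched():
    """Substrate index-matched to the ambient: no interface (beta = 0, r = 0)."""
    return OpticalConstants(wavelength=532.0, eps_substrate=1.0 + 0.0j)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150913)
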