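import numpy as np
import pytest

from cestnoe.bloch import default_brain_model, simulate_zspectrum
from cestnoe.core import SaturationParams
from cestnoe.io import default_grid
from cestnoe.lorentz import fit_multipool


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def sat():
    return SaturationParams(B1_uT=1.0, t_sat=5.0)


@pytest.fixture(scope="session")
def brain_model():
    return default_brain_model()


@pytest.fixture(scope="session")
def brain_spectrum(brain_model, sat, grid):
    """Noiseless seven-pool brain-like Z-spectrum."""
    return simulate_zspectrum(brain_model, sat, grid)


@pytest.fixture(scope="session")
def brain_fit(brain_spectrum):
    fit = fit_multipool(brain_spectrum)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
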