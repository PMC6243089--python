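import warnings

import numpy as np
import pytest

from ir2d.kubo import FFCFParams, SpectralComponent
from ir2d.simulate import MixtureModel, reference_model, simulate_tw_series

warnings.filterwarnings("ignore", category=UserWarning, module="ir2d")

WT_FFCF = FFCFParams(1.6, 3.0, 20.7, 4.1, 16.0)
PDX_LOW_FFCF = FFCFParams(2.2, 2.0, 31.7, 1.8, 13.0)
L358P_LOW_FFCF = FFCFParams(3.4, 2.6, 30.5, 2.5, 13.0)


@pytest.fixture(scope="session")
def wide_axis():
    return np.linspace(1890.0, 1990.0, 2001)


@pytest.fixture(scope="session")
def wt_model():
    return reference_model("wt")


@pytest.fixture(scope="session")
def pdx_model():
    return reference_model("pdx")


@pytest.fixture(scope="session")
def l358p_model():
    return reference_model("l358p")


@pytest.fixture(scope="session")
def wt_series(wt_model):
    """Noiseless waiting-time series of the free enzyme (expensive; shared)."""
    return simulate_tw_series(wt_model)


@pytest.fixture(scope="session")
def pdx_series(pdx_model):
    return simulate_tw_series(pdx_model)


@pytest.fixture(scope="session")
def wt_linear(wt_model, wide_axis):
    return wt_model.linear_spectrum(wide_axis)


@pytest.fixture(scope="session")
def pdx_linear(pdx_model):
    return pdx_model.linear_spectrum(np.linspace(1900.0, 1970.0, 701))


@pytest.fixture(scope="session")
def single_band_model():
    """Generic noiseless single-component model on the default axes."""
    return MixtureModel((SpectralComponent(1935.0, WT_FFCF),))
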