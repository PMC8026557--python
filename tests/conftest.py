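import numpy as np
import pytest

from voigtkit import VoigtShape


@pytest.fixture(scope="session")
def xi_grid():
    """Line-damping values spanning Gaussian to Lorentzian dominance."""
    return [0.001, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0]


@pytest.fixture(scope="session")
def v_grid():
    return np.linspace(-6.0, 6.0, 25)


@pytest.fixture()
def unit_shape():
    return VoigtShape(center=0.0, gauss_width=1.0, xi=0.5, area=1.0)
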