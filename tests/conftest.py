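import numpy as np
import pytest

from viscsf.csf_models import PolynomialCSF, PyramidCSF
from viscsf.display import DisplayModel
from viscsf.stimulus import MiraSpec


@pytest.fixture
def display():
    return DisplayModel()


@pytest.fixture
def mira_spec():
    return MiraSpec(
        width_px=432,
        height_px=432,
        diameter_px=400,
        kaiser_beta=6.0,
        period_px=40.0,
        background_level=120,
        modulation_amplitude=40.0,
    )


@pytest.fixture
def pyramid_truth():
    # plausible slopes: sensitivity falls with k and f, rises with luminance
    return PyramidCSF(c0=2.0, c_f=-0.02, c_k=-0.05, c_L=0.3)


@pytest.fixture
def quartic_template():
    return PolynomialCSF(order=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
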