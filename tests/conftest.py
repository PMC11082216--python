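import numpy as np
import pytest

from cdgsensor import FourSiteModelParams, ITCProtocol, SensorIsothermParams

# Published calibration of the two sensor variants (497-nm excitation channel)
CDGREEN_497 = dict(bottom=1.0, top=12.0, kd=214e-9, hill=2.30)
CDGREEN_405 = dict(bottom=1.0, top=5.0, kd=225e-9, hill=-2.43)
CDGREEN2_497 = dict(bottom=1.0, top=8.2, kd=1.24e-6, hill=1.86)

ITC_FITTED = dict(K1=3.98e8, K3=6.05e5, dH1=-16.2, dH3=-7.5, f=0.96)


@pytest.fixture
def cdgreen_497():
    return SensorIsothermParams(**CDGREEN_497)


@pytest.fixture
def cdgreen2_497():
    return SensorIsothermParams(**CDGREEN2_497)


@pytest.fixture
def itc_params():
    return FourSiteModelParams(**ITC_FITTED)


@pytest.fixture
def itc_protocol():
    return ITCProtocol.default_cdg()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
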