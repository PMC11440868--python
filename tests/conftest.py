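import numpy as np
import pytest

from frickedose import FrickeConstants, SynthConfig

#: 24 h Fricke doses (Gy) measured for the six administered activities (MBq);
#: the published calibration series used throughout the calibration tests.
CALIBRATION_ACTIVITIES_MBQ = np.array([15.0, 20.0, 30.0, 40.0, 60.0, 80.0])
CALIBRATION_DOSES_GY = np.array([2.34, 3.70, 5.33, 7.71, 10.61, 12.51])


@pytest.fixture
def calibration_series():
    return CALIBRATION_ACTIVITIES_MBQ, CALIBRATION_DOSES_GY


@pytest.fixture
def f18_constants():
    return FrickeConstants.for_f18()


@pytest.fixture
def co60_constants():
    return FrickeConstants.for_co60()


@pytest.fixture
def synth_cfg():
    return SynthConfig(seed=42)


@pytest.fixture
def noiseless_cfg():
    return SynthConfig(seed=42, od_noise_cv=0.0, pet_noise_cv=0.0)
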