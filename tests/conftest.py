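import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from plumetrack.dispersion import (
    DispersionState,
    SourceTerm,
    WindSeries,
)

# Emulated study conditions used across the suite.
RATE = 4.65e-3       # kg/s
STACK = 83.8         # m
WIND_SPEED = 1.85    # m/s
WIND_FROM = 210.0    # deg


@pytest.fixture
def source():
    return SourceTerm.constant(RATE, height=STACK)


@pytest.fixture
def wind():
    return WindSeries.constant(WIND_SPEED, WIND_FROM)


@pytest.fixture
def midstate():
    return DispersionState.midrange()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
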