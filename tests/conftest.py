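import dataclasses

import pytest

from leafphys.recording import ProtocolSpec
from leafphys.simulate import (
    BSC_CHANNEL_PARAMS,
    MC_CHANNEL_PARAMS,
    simulate_recording,
)


@pytest.fixture(scope="session")
def bsc_params():
    return BSC_CHANNEL_PARAMS


@pytest.fixture(scope="session")
def mc_params():
    return MC_CHANNEL_PARAMS


@pytest.fixture(scope="session")
def noiseless_bsc_params():
    return dataclasses.replace(BSC_CHANNEL_PARAMS, current_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_mc_params():
    return dataclasses.replace(MC_CHANNEL_PARAMS, current_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def noiseless_bsc_recording(noiseless_bsc_params, default_protocol):
    return simulate_recording(noiseless_bsc_params, default_protocol, seed=7)


@pytest.fixture(scope="session")
def bsc_recording(default_protocol):
    return simulate_recording(BSC_CHANNEL_PARAMS, default_protocol, seed=7)
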