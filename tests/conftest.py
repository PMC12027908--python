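import numpy as np
import pytest

from diastolica.waveform import WaveformParams, simulate_waveform


@pytest.fixture(scope="session")
def noiseless_params() -> WaveformParams:
    return WaveformParams(noise_sd=0.0, resp_amplitude=0.0)


@pytest.fixture(scope="session")
def noiseless_waveform(noiseless_params):
    return simulate_waveform(noiseless_params)


@pytest.fixture(scope="session")
def default_waveform():
    return simulate_waveform(WaveformParams(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
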