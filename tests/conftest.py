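import numpy as np
import pytest

from iglu import NoiseModel, RecordingProtocol, SynapseConfig


@pytest.fixture
def quiet_noise():
    return NoiseModel(sigma=0.0)


@pytest.fixture
def snr8_noise():
    """Unit noise SD; pair with quantal_amp=8 for SNR 8 recordings."""
    return NoiseModel(sigma=1.0)


@pytest.fixture
def stim_train():
    """20 stimuli at 0.2 Hz starting at 5 s (after a full baseline window)."""
    return tuple(5.0 + 5.0 * i for i in range(20))


@pytest.fixture
def evoked_protocol(stim_train):
    return RecordingProtocol(duration=105.0, stim_times=stim_train)


def fixed_amp_config(pr, quantal_amp=8.0, spont_rate=0.0):
    return SynapseConfig(pr=pr, spont_rate=spont_rate, quantal_amp=quantal_amp, amp_cv=0.0)
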