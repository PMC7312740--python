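import numpy as np
import pytest

from nodulebci.containers import EEGRecording, Epoch, Event


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """8-channel, 10 s, 256 Hz random recording with a few events."""
    data = rng.standard_normal((8, 2560))
    events = [Event(sample=s, identity=i, is_target=(i % 6 == 0))
              for i, s in enumerate(range(256, 2304, 256))]
    return EEGRecording(data=data, fs=256.0, events=events)


def make_epoch(data, fs=256.0, is_target=False, identity=0, t0_offset_ms=-200.0):
    return Epoch(data=np.asarray(data, dtype=float), fs=fs,
                 is_target=is_target, identity=identity,
                 t0_offset_ms=t0_offset_ms)


@pytest.fixture
def tone_epoch():
    """Two-channel 10 Hz tone epoch, 1 s at 256 Hz."""
    t = np.arange(256) / 256.0
    x = np.vstack([np.cos(2 * np.pi * 10 * t),
                   np.sin(2 * np.pi * 10 * t)])
    return make_epoch(x)
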