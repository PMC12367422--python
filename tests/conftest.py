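import numpy as np
import pytest

from spikewave.recording import Recording
from spikewave.synth import SimConfig, inject_events, make_background


@pytest.fixture(scope="session")
def small_sim():
    """One small injected recording with its truth log (2 ch x 2 min)."""
    cfg = SimConfig(n_channels=2, duration=120.0, seed=42)
    rec, truth = inject_events(make_background(cfg), cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sine_recording(freq_hz, fs=512.0, duration=30.0, amp=100.0, n_channels=1):
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (n_channels, 1))
    return Recording(data=data, fs=fs, ch_names=[f"CH{i:03d}" for i in range(n_channels)])
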