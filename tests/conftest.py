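import numpy as np
import pytest

from corticothal.data import EpochedRecording


@pytest.fixture(scope="session")
def time_axis():
    fs = 250.0
    t = np.arange(-2.0, 2.0001, 1.0 / fs)
    return t, fs


@pytest.fixture()
def sinusoid_recording(time_axis):
    """Single-trial pure cosine factory: (freq, phase_at, t0, amp) -> recording."""
    t, fs = time_axis

    def make(freq=8.0, phi0=0.0, t0=0.0, amp=1.0, n_trials=1):
        x = amp * np.cos(2 * np.pi * freq * (t - t0) + phi0)
        data = np.tile(x, (n_trials, 1, 1))
        return EpochedRecording(
            data=data, time=t, fs=fs, channel_labels=["a"],
            outcome=np.ones(n_trials, dtype=np.uint8),
        )

    return make


@pytest.fixture()
def two_channel_noise(time_axis):
    """Two-channel recording factory with channel b = delayed a + noise."""
    from corticothal.synthetic import _powerlaw_noise

    t, fs = time_axis

    def make(lag_samples=5, n_trials=60, seed=0, noise_ratio=1.0):
        rng = np.random.default_rng(seed)
        a = _powerlaw_noise(rng, (n_trials, t.size), 1.0, fs)
        b = np.roll(a, lag_samples, axis=-1)
        if noise_ratio > 0:
            b = b + noise_ratio * _powerlaw_noise(rng, (n_trials, t.size), 1.0, fs)
        return EpochedRecording(
            data=np.stack([a, b], axis=1), time=t, fs=fs,
            channel_labels=["a", "b"],
            outcome=(rng.random(n_trials) < 0.7).astype(np.uint8),
        )

    return make
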