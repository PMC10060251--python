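import numpy as np
import pytest

from tbpc.io import EEGRecording
from tbpc.simulate import spherical_cap_montage


@pytest.fixture(scope="session")
def fs() -> float:
    return 250.0


@pytest.fixture()
def tone_recording(fs) -> EEGRecording:
    """Four sinusoidal channels (6, 10, 20, 40 Hz) at 30 s."""
    t = np.arange(0, 30.0, 1.0 / fs)
    data = np.vstack([20 * np.sin(2 * np.pi * f * t) for f in (6, 10, 20, 40)])
    return EEGRecording(data, fs, ["c1", "c2", "c3", "c4"])


@pytest.fixture()
def noise_recording(fs) -> EEGRecording:
    """Sixteen i.i.d. Gaussian channels, 30 s."""
    rng = np.random.default_rng(7)
    data = rng.normal(0, 10, size=(16, int(30 * fs)))
    labels = [f"n{i:02d}" for i in range(16)]
    return EEGRecording(data, fs, labels)


@pytest.fixture(scope="session")
def small_montage():
    return spherical_cap_montage(8)
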