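import numpy as np
import pytest

from alphashift import default_montage
from alphashift.simulate import Recording


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_rest_recording(r, duration_s=60.0, fs=250.0, alpha_hz=10.0,
                        noise_sd=0.3, amp=1.0, seed=0, label="Pz"):
    """Single-channel resting oscillation with slow amplitude fluctuation.

    Built directly from the signal model (independent of the simulator's
    subject machinery): y = A(t) * (cos(2 pi f t + phi) + r) + noise, where
    A(t) is a low-passed positive random fluctuation around ``amp``.
    """
    from alphashift.filters import zero_phase_butterworth

    g = np.random.default_rng(seed)
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    slow = zero_phase_butterworth(g.standard_normal(n), fs, "lowpass", 0.2, 2)
    slow = slow / slow.std() * 0.35
    a = amp * np.clip(1.0 + slow, 0.05, None)
    y = a * (np.cos(2 * np.pi * alpha_hz * t + g.uniform(0, 2 * np.pi)) + r)
    if noise_sd > 0:
        from alphashift.simulate import oneoverf_noise
        y = y + noise_sd * oneoverf_noise(n, fs, 1.0, g)
    return Recording(y[np.newaxis, :], fs, [label], [], "other"), a
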