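import numpy as np
import pytest


def brute_force_sampen(x, m, r):
    """Independent O(N^2) sample-entropy oracle: explicit template-pair
    counting with Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n_templ = len(x) - m
    B = A = 0
    for i in range(n_templ):
        for j in range(i + 1, n_templ):
            if np.max(np.abs(x[i:i + m] - x[j:j + m])) <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -np.log(A / B)


@pytest.fixture
def sampen_oracle():
    return brute_force_sampen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def spectral_noise_ref(n, beta, rng):
    """Reference f^-beta noise generator, independent of the package's."""
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2)
    y = np.fft.irfft(amp * np.exp(1j * rng.uniform(0, 2 * np.pi, len(f))), n)
    return (y - y.mean()) / y.std()


@pytest.fixture
def pink_noise():
    def _make(n, seed=0, beta=1.0):
        return spectral_noise_ref(n, beta, np.random.default_rng(seed))
    return _make
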