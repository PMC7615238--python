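import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def pink_noise(rng) -> np.ndarray:
    """120 s of 1/f-shaped noise at 500 Hz (unit-free test signal)."""
    n = 60000
    spectrum = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1 / 500.0)
    shape = np.maximum(f, 0.5) ** -0.5
    shape[0] = 0.0
    x = np.fft.irfft(spectrum * shape, n=n)
    return x / np.sqrt(np.mean(x**2)) * 30.0
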