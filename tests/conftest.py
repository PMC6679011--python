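import numpy as np
import pytest

from nucleophys import DetectionVolume, SimSpec, five_nucleoli_cell, simulate_trace


@pytest.fixture(scope="session")
def volume():
    return DetectionVolume(w=0.2, s=5.0)


@pytest.fixture(scope="session")
def five_cell():
    """Noiseless reference phantom, shared across tests (read-only)."""
    return five_nucleoli_cell(seed=0)


@pytest.fixture(scope="session")
def short_trace(volume):
    """A 0.2 s single-component trace (1e5 samples) for correlator tests."""
    return simulate_trace(SimSpec(duration=0.2, seed=11), volume)


def direct_g(counts: np.ndarray, k: int) -> float:
    """Independent brute-force '+1' autocorrelation at integer lag k."""
    mu = counts.mean()
    d = counts - mu
    n = counts.size
    return float(np.dot(d[: n - k], d[k:]) / (n - k) / (mu * mu) + 1.0)
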