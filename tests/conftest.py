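import numpy as np
import pytest

import wavecal as wc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def seven_band():
    """Canonical seven-band composite signal and its generating spec."""
    spec = wc.seven_band_spec()
    composite, parts = wc.compose_signal(spec)
    return spec, composite, parts


@pytest.fixture(scope="session")
def small_recovery():
    """A small regression dataset with known informative bands (fast tests)."""
    spec = wc.recovery_spec()
    data, truth = wc.make_regression_dataset(spec, 16, seed=777)
    return spec, data, truth


def strict_local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    v = np.asarray(values)
    return np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
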