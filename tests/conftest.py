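import warnings

import numpy as np
import pytest

from andesdyn.series import ProxyTimeSeries
from andesdyn.synthetic import generate_coupled, northern_like, southern_like


@pytest.fixture(scope="session")
def northern_data():
    """Observed coupled series from the climate-driven preset (seed 11)."""
    return generate_coupled(northern_like(seed=11))


@pytest.fixture(scope="session")
def southern_data():
    """Observed coupled series from the warfare-driven preset (seed 11)."""
    return generate_coupled(southern_like(seed=11))


@pytest.fixture
def noisy_sinusoid():
    rng = np.random.default_rng(42)
    t = np.arange(100)
    y = np.sin(2 * np.pi * t / 30) + 0.2 * rng.standard_normal(100)
    return ProxyTimeSeries(t, y, label="noisy sinusoid")


@pytest.fixture(autouse=True)
def _quiet_perfect_fit_warnings():
    """Perfect fits on noise-free data legitimately warn; keep logs readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*perfect fit.*", category=RuntimeWarning
        )
        yield
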