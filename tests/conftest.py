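import numpy as np
import pytest

import cpdesign as cp


@pytest.fixture
def default_shape() -> cp.ShapeParams:
    """MMSE-inspired trajectory: (25, -1, -2), change-point 5, sigma^2 = 5."""
    return cp.ShapeParams(alpha=25.0, beta=-1.0, delta=-2.0,
                          change_point=5.0, tau=0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(default_shape) -> cp.LongitudinalDataset:
    """30 individuals under the default design with moderate drop-out."""
    scenario = cp.Scenario(n=30, shape=default_shape, p_d=0.3, seed=42)
    return cp.simulate_dataset(scenario)


@pytest.fixture
def short_settings() -> cp.ChainSettings:
    """Shortened chain for unit tests (same sweep, fewer iterations)."""
    return cp.ChainSettings(iterations=8_000, burn_in=500, thin=10, seed=7)
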