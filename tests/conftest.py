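import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_system():
    """A small simulated seasonal system shared by read-only tests."""
    from vegcarry.simulate import SeasonalSystemConfig, simulate_seasonal_system

    return simulate_seasonal_system(SeasonalSystemConfig(n_cells=20, n_years=35, seed=11))
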