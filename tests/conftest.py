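import numpy as np
import pytest

from signalsim import BuildFlags, SimConfig, run


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Trigger JIT compilation once so per-test timings stay meaningful."""
    run(SimConfig(n_steps=2, n_food_init=50, n_display_init=50,
                  flags=BuildFlags(items_needed=True), seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast, fully featured configuration for behavioral tests."""
    return SimConfig(
        n_steps=120,
        n_food_init=400,
        n_display_init=400,
        seed=42,
    )
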