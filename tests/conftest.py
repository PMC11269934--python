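import numpy as np
import pytest

from devwindow.simulate import simulate_patch_sweeps

DEFAULT_CELL = {"vrest": -60.0, "rm": 500.0, "cm": 100.0, "threshold": -45.0, "it": 1.5}


@pytest.fixture(scope="session")
def patch_noiseless():
    """Noise-free patch-clamp sweep families for the default model cell."""
    sweep_sets, truth = simulate_patch_sweeps(dict(DEFAULT_CELL), noise=0.0, seed=3)
    return sweep_sets, truth.iloc[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
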