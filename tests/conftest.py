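import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """Tiny noisy phantom with truth: 10^3 grid, 8 channels, 16 volumes."""
    from mccdenoise import default_phantom, simulate_mcc

    cfg = default_phantom("mini", channels=8, seed=3)
    cfg.grid_shape = (10, 10, 10)
    cfg.shell_counts = (2, 4, 4, 6)
    return simulate_mcc(cfg)
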