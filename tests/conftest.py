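import numpy as np
import pytest

from midfuse import synthetic


@pytest.fixture(scope="session")
def small_panel():
    """Default-structure panel with a reduced NIR grid for fast tests."""
    cfg = synthetic.SimConfig(seed=7, nir_points=150)
    return synthetic.generate_panel(cfg, task="species")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
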