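import numpy as np
import pytest

from cosmofret import SimConfig


@pytest.fixture
def clean_cfg():
    """Noise-free, fully labeled, bleach-free configuration for exact tests."""
    return SimConfig(n_locations=40, n_control_locations=0, seed=11,
                     noise_sd=0.0, efret_sd=0.0, bleach_rate=0.0)


@pytest.fixture
def make_cfg():
    def _make(**kw):
        base = dict(n_locations=40, n_control_locations=0, seed=11)
        base.update(kw)
        return SimConfig(**base)
    return _make


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))
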