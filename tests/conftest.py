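import numpy as np
import pytest

from dyskpipe.synthdata import SynthConfig


@pytest.fixture
def cfg() -> SynthConfig:
    """Small, fast configuration used across module tests."""
    return SynthConfig(seed=1234, n_units=10, pulses_per_power=100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240717)
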