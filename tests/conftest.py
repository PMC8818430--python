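import logging

import numpy as np
import pytest

from vi_emdar.synth import SynthConfig, generate_dataset

# The max-IMF warning is expected on narrowband inputs; keep test output clean.
logging.getLogger("vi_emdar.emd").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fs1k_time():
    """4 s time axis at 1 kHz (the study's epoch geometry)."""
    return np.arange(4000) / 1000.0


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic two-class dataset (defaults otherwise)."""
    return generate_dataset(SynthConfig(n_trials_per_class=12, seed=42))


@pytest.fixture(scope="session")
def tiny_cfg():
    """Fast generator config: 4 s epochs at 250 Hz."""
    return SynthConfig(n_trials_per_class=10, fs=250.0, seed=5)
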