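import numpy as np
import pytest

from pkjburst.calibration import load_preset, preset_names
from pkjburst.synthetic import TonicParams, generate_tonic_train


@pytest.fixture(scope="session")
def presets():
    """All packaged calibrated regimes, loaded once."""
    return {name: load_preset(name) for name in preset_names()}


@pytest.fixture(scope="session")
def tonic_train_50hz():
    """A plain 50 spikes/s gamma-renewal train (k=4, no drift), 300 s."""
    return generate_tonic_train(TonicParams(50.0, 4.0), 300.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
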