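import numpy as np
import pytest

from limbkin import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario():
    """Small default-layout scenario used across tests."""
    return synth.default_scenario(n_participants=20, seed=11)


@pytest.fixture(scope="session")
def clean_walk(scenario):
    """One noise-free synthetic walk with planted (-20 deg, 0.90)."""
    row = {"limb_angle_ext": -20.0, "limb_length": 0.90}
    series, truth = synth.synthesize_walk(row, scenario, noise_sd_px=0.0)
    return series, truth
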