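import numpy as np
import pytest

from framelock import ModulationConfig, make_phantom, simulate_stack


@pytest.fixture(scope="session")
def letters_scene():
    return make_phantom((64, 64), "letters", seed=7)


@pytest.fixture(scope="session")
def dual_config():
    return ModulationConfig()  # 12/6 Hz at 48 fps, 24 frames


@pytest.fixture(scope="session")
def dual_stack(letters_scene, dual_config):
    return simulate_stack(letters_scene, dual_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
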