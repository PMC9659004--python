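import numpy as np
import pytest

from virocount import OpticsModel


@pytest.fixture
def quiet_optics() -> OpticsModel:
    """Noise-free camera: exact flux bookkeeping."""
    return OpticsModel(background_level=0.0, background_gradient=0.0,
                       camera_offset=0.0, read_noise_sd=0.0,
                       shot_noise=False)


@pytest.fixture
def default_optics() -> OpticsModel:
    return OpticsModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
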