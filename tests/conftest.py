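import numpy as np
import pytest

from sporeloc import ForesporeModel, ImagingConfig, LocusPlacementModel


@pytest.fixture
def forespore():
    return ForesporeModel()  # 600-nm sphere


@pytest.fixture
def free_placement():
    return LocusPlacementModel(mode="free")


@pytest.fixture
def noiseless_cfg():
    """Deterministic render: no shot noise, no read noise, no background."""
    return ImagingConfig(shot_noise=False, read_noise_sd=0.0, background_level=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
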