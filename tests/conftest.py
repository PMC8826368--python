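import numpy as np
import pytest

from hemovis import PipelineConfig, ViewingGeometry, default_montage
from hemovis.preprocessing import OpticalDensity
from hemovis.simulate import subset_montage

FS = 10.2


@pytest.fixture
def geom():
    return ViewingGeometry()


@pytest.fixture
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture
def small_montage():
    """A 4-channel slice of the adult montage, for fast synthetic tests."""
    return subset_montage(default_montage("adult"), 4)


@pytest.fixture
def child_montage_small():
    return subset_montage(default_montage("child"), 5)


def od_from_series(x: np.ndarray, fs: float = FS) -> OpticalDensity:
    """Wrap a 1-D series as a single-channel, two-wavelength OD object."""
    return OpticalDensity(od=np.tile(x, (1, 2, 1)), fs=fs)
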