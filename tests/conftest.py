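import numpy as np
import pytest

from petrad import phantom
from petrad.quantization import DiscretizationConfig, GrayLevelVolume
from petrad.volumes import RegionMask, SUVVolume


@pytest.fixture(scope="session")
def default_phantom():
    """One noise-free heterogeneous phantom with its ground-truth masks."""
    spec = phantom.default_phantom_spec()
    return spec, *phantom.generate_phantom(spec)


def make_gray(levels, bins, mask=None):
    """Wrap an integer level array as a GrayLevelVolume (full-grid mask default)."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    levels = np.where(mask, levels, 0)
    return GrayLevelVolume(
        levels=levels,
        config=DiscretizationConfig(lower=0.0, upper=float(bins), bins=bins),
        mask=RegionMask(mask),
    )


def random_gray(rng, bins, max_side=5):
    """Random small VOI: random levels and a random (non-empty) mask."""
    shape = tuple(rng.integers(1, max_side + 1, size=3))
    levels = rng.integers(1, bins + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    return make_gray(levels, bins, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
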