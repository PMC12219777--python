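import numpy as np
import pytest

import deshvol as dv


@pytest.fixture(scope="session")
def preset_runs():
    """Noiseless image + truth for every phantom preset (generated once)."""
    out = {}
    for name in dv.phantom.PRESET_NAMES:
        spec = dv.preset(name)
        image, truth = dv.generate_phantom(spec)
        out[name] = (spec, image, truth)
    return out


@pytest.fixture(scope="session")
def inph_noiseless(preset_runs):
    return preset_runs["inph"]


@pytest.fixture(scope="session")
def mixture_image():
    """Two-component Gaussian mixture: means 100/300, sd 20, >=1e5 voxels."""
    rng = np.random.default_rng(7)
    shape = (50, 50, 50)  # 125000 voxels
    comp = rng.random(shape) < 0.5
    data = np.where(comp, rng.normal(100.0, 20.0, shape), rng.normal(300.0, 20.0, shape))
    image = dv.ImageVolume(data, (1.0, 1.0, 1.0))
    mask = dv.BinaryMask(np.ones(shape, dtype=bool), (1.0, 1.0, 1.0))
    return image, mask
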