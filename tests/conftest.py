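import numpy as np
import pytest

from ctpstroke.perfusion import estimate_maps
from ctpstroke.phantom import (
    GridSpec,
    brain_mask_for_grid,
    build_phantom,
    geometry_for_volumes,
)


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def brain(grid):
    return brain_mask_for_grid(grid)


@pytest.fixture(scope="session")
def noiseless_phantom(grid, brain):
    """Default noiseless acquisition: 83.3 ml lesion with a 27.8 ml core."""
    geom, capped = geometry_for_volumes(83.3, 27.8, grid, brain=brain)
    assert not capped
    return build_phantom(geom, grid=grid, noise_sigma=0.0, seed=0, brain=brain)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    return estimate_maps(noiseless_phantom)


@pytest.fixture(scope="session")
def aif_curve(grid, noiseless_phantom):
    return noiseless_phantom.aif_curve()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230901)
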