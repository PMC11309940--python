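import numpy as np
import pytest
from shapely.geometry import box

from metanets.landscape_io import GridTransform, HabitatMask, Patch, PatchLayer
from metanets.synthetic_data import LandscapeParams, simulate_study

# small landscape for tests that only need plausible geometry, not study power
SMALL_LANDSCAPE = LandscapeParams(
    extent=(18_000.0, 18_000.0), n_clusters=3, patches_per_cluster=(5, 7)
)


def square_layer(coords, timestep=0, size=1.0):
    """Unit-square patch layer at given lower-left corners."""
    patches = [
        Patch(patch_id=f"p{k:04d}", geometry=box(x, y, x + size, y + size),
              area=size * size)
        for k, (x, y) in enumerate(coords)
    ]
    return PatchLayer(timestep_label=timestep, patches=patches)


def random_mask_series(rng, n_steps=4, shape=(12, 12), p=0.3, cell=10.0):
    t = GridTransform(x0=0.0, y0=shape[0] * cell, cell=cell)
    return [
        HabitatMask(grid=(rng.random(shape) < p).astype(np.uint8), transform=t,
                    timestep_label=k)
        for k in range(n_steps)
    ]


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study at reduced scale (historical regime)."""
    return simulate_study(7, regime="historical", landscape=SMALL_LANDSCAPE)


@pytest.fixture(scope="session")
def default_study():
    """One deterministic synthetic study at the default (study) scale."""
    return simulate_study(11, regime="historical")
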