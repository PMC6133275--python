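import numpy as np
import pytest

from virtualsdm.rasters import (
    EnvGenSpec,
    GridDef,
    Layer,
    RasterStack,
    generate_synthetic_env,
    worldclim_like,
)


@pytest.fixture(scope="session")
def small_stack() -> RasterStack:
    """5 moderately correlated standardized layers on a 60x60 rectangle."""
    R = np.full((5, 5), 0.5)
    np.fill_diagonal(R, 1.0)
    spec = EnvGenSpec(
        n_layers=5,
        grid=GridDef(nrows=60, ncols=60),
        target_corr=R,
        spatial_range=6.0,
        mask_style="rectangle",
        seed=11,
    )
    return generate_synthetic_env(spec)


@pytest.fixture(scope="session")
def preset_stack() -> RasterStack:
    """The 19-layer collinear preset on a reduced 120x120 grid."""
    return generate_synthetic_env(worldclim_like(nrows=120, ncols=120, seed=5))


def make_layer(values, nodata=-9999.0):
    """Layer from a 2-D list; NaN entries become masked-false."""
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    grid = GridDef(nrows=arr.shape[0], ncols=arr.shape[1], nodata=nodata)
    return Layer(grid, arr, mask)
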