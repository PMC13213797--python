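import numpy as np
import pytest

from monomech import (
    AcquisitionSpec,
    IslandRecipe,
    SubstrateSpec,
    VectorField2D,
    gen_island_traction,
    gen_speckle_image,
)

PIXEL_SIZE = 0.65  # um/px


@pytest.fixture(scope="session")
def speckle_frame():
    """A textured bead image used by the flow/DIC fixtures."""
    return gen_speckle_image((256, 256), 0.05, PIXEL_SIZE, seed=11)


@pytest.fixture(scope="session")
def island():
    """Default contractile-island fixture: (traction, stress oracle, mask)."""
    return gen_island_traction(IslandRecipe())


@pytest.fixture(scope="session")
def substrate():
    return SubstrateSpec()  # 4.8 kPa, nu = 0.49, h = 100 um


@pytest.fixture
def acquisition():
    return AcquisitionSpec(PIXEL_SIZE, 6.0, 41)


def uniform_shift_field(shape, shift_px, pixel_size=PIXEL_SIZE):
    """A constant displacement field of ``shift_px`` (x, y) pixels in um."""
    return VectorField2D(
        np.full(shape, shift_px[0] * pixel_size),
        np.full(shape, shift_px[1] * pixel_size),
        pixel_size,
        "um",
    )
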