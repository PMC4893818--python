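import numpy as np
import pytest

from lysoquant import (
    CellMask,
    SyntheticCellSpec,
    generate_cell,
    segment_cell,
    subtract_background,
)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticCellSpec:
    """A compact cell that keeps rendered tests fast."""
    return SyntheticCellSpec(
        image_size=128, cell_radius_px=45.0, n_puncta=60, seed=7
    )


@pytest.fixture(scope="session")
def clean_spec(small_spec) -> SyntheticCellSpec:
    """Noise-free variant for tests that need exact intensities."""
    import dataclasses

    return dataclasses.replace(
        small_spec, noise_gaussian_sd=0.0, noise_poisson=False
    )


@pytest.fixture(scope="session")
def rendered_cell(small_spec):
    """One rendered cell with ground truth, shared across tests."""
    return generate_cell(small_spec)


@pytest.fixture(scope="session")
def segmented_cell(rendered_cell):
    stack, truth = rendered_cell
    frame = stack.frame("LAMP1", 0)
    mask = segment_cell(frame)
    return subtract_background(frame, mask), mask, truth


@pytest.fixture
def disk_mask() -> CellMask:
    """Centred disk of radius 50 in a 128x128 grid."""
    yy, xx = np.mgrid[0:128, 0:128]
    return CellMask(np.hypot(xx - 63.5, yy - 63.5) <= 50)
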