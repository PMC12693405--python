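import numpy as np
import pytest

from podosem.io import PolygonRoi, rasterize_roi
from podosem.preprocess import BlurParams
from podosem.ridge import RidgeParams
from podosem.simulate import PatternSpec, make_pattern


@pytest.fixture(scope="session")
def default_roi():
    """Inset rectangular ROI for the default 256x256 pattern."""
    return PolygonRoi([(8, 8), (247, 8), (247, 247), (8, 247)], label="roi")


@pytest.fixture(scope="session")
def default_roi_mask(default_roi):
    return rasterize_roi(default_roi, (256, 256))


@pytest.fixture(scope="session")
def matched_params():
    """Ridge parameters matched to the default simulated slit scale
    (~16.5 px grooves at 0.01 µm/px)."""
    return RidgeParams(sigma=4.0, line_width=30.0, lower_threshold=0.01,
                       upper_threshold=0.02, min_line_length=5.0)


@pytest.fixture(scope="session")
def matched_blur():
    return BlurParams(radius=2.0)


@pytest.fixture(scope="session")
def noisy_pattern(default_roi_mask):
    """One realistic default-condition pattern with its truth."""
    spec = PatternSpec(orientation=15.0, curvature=0.1, seed=11)
    image, truth = make_pattern(spec, roi_mask=default_roi_mask)
    return spec, image, truth
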