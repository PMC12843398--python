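import math

import numpy as np
import pytest

from pesrnfl.config import RunConfig
from pesrnfl.landmarks import OcularParameters
from pesrnfl.phantom import PhantomSpec, render_phantom
from pesrnfl.pipeline import PipelineContext
from pesrnfl.preprocess import FundusImage


CANONICAL_PARAMS = OcularParameters(
    onh_x=15.0, onh_y=2.0,
    onh_fo_angle=math.degrees(math.atan2(2.0, 15.0)),
    ellipticity=0.88, onh_area=38.45)


@pytest.fixture(scope="session")
def ctx() -> PipelineContext:
    return PipelineContext.build(RunConfig())


@pytest.fixture(scope="session")
def small_phantom():
    """One 480x720 phantom with ground truth (fast; for unit tests)."""
    return render_phantom(PhantomSpec(resolution=(480, 720), seed=11))


@pytest.fixture()
def flat_image():
    """Uniform mid-gray disk on black: a valid but featureless fundus."""
    h, w = 240, 360
    rows, cols = np.mgrid[0:h, 0:w]
    roi = (rows - h / 2) ** 2 + (cols - w / 2) ** 2 <= (0.45 * w) ** 2
    return FundusImage(pixels=np.where(roi, 0.5, 0.0), roi_mask=roi)


def make_image(pixels, roi=None, **kw) -> FundusImage:
    pixels = np.asarray(pixels, dtype=float)
    if roi is None:
        roi = np.ones(pixels.shape, dtype=bool)
    return FundusImage(pixels=pixels, roi_mask=roi, **kw)
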