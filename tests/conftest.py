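import pytest

from balbiani import PixelCalibration, SceneParams
from balbiani.core import Image2D, median_filter
from balbiani.disassembly import segment_oocyte
from balbiani.synth import make_scene, render_scene

# analysis-scale calibrations used throughout the suite (the pipeline default
# is 0.35 µm/px; tests use coarser sampling to keep scene sizes moderate)
CAL_RATIO = PixelCalibration(xy_um_per_px=0.7)
CAL_PUNCTA = PixelCalibration(xy_um_per_px=0.5)


@pytest.fixture(scope="session")
def cal07() -> PixelCalibration:
    return CAL_RATIO


@pytest.fixture(scope="session")
def cal05() -> PixelCalibration:
    return CAL_PUNCTA


def dapi_projection(stack):
    """DAPI sum projection + 5-px median, the boundary-segmentation input."""
    img = Image2D(stack.channel("DAPI").sum(axis=0), stack.calibration)
    return median_filter(img, 5)


def boundary_of(stack):
    return segment_oocyte(dapi_projection(stack))


@pytest.fixture(scope="session")
def intact_scene():
    """A 110 µm oocyte with an intact Bb (f=1), noisy render at SNR 10."""
    scene = make_scene(SceneParams(oocyte_diameter_um=110.0), seed=7, calibration=CAL_RATIO)
    return scene, render_scene(scene)


@pytest.fixture(scope="session")
def intact_scene_clean():
    """Same geometry rendered without noise."""
    scene = make_scene(SceneParams(oocyte_diameter_um=110.0), seed=7, calibration=CAL_RATIO)
    return scene, render_scene(scene, with_noise=False, n_slices=1)
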