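import numpy as np
import pytest

from gingired import Photo, RoiGroundTruth, RoiSpec, generate_roi
from gingired.synthetic import HaloSpec, halo_radius_for_fraction


@pytest.fixture
def gingiva_roi():
    """Factory: a gingiva-toned synthetic ROI patch."""

    def make(true_rg=1.7, noise_sd=4.0, halo_frac=None, seed=0, size=96):
        halo = None
        if halo_frac is not None:
            r = halo_radius_for_fraction(halo_frac, size, size)
            halo = HaloSpec(cx=size / 2, cy=size / 2, radius=r)
        gt = RoiGroundTruth(true_rg=true_rg, noise_sd=noise_sd, halo=halo, seed=seed)
        return generate_roi(gt, width=size, height=size)

    return make


@pytest.fixture
def checker_photo():
    """A tiny photo with hand-known pixels for crop arithmetic."""
    px = np.arange(4 * 6 * 3, dtype=np.uint8).reshape(4, 6, 3)
    return Photo(photo_id="checker", pixels=px)


@pytest.fixture
def whole_photo_spec():
    def make(photo, site="U_11_21", timepoint="BO"):
        return RoiSpec(photo_id=photo.photo_id, site=site, timepoint=timepoint,
                       rect=(0, 0, photo.width, photo.height))

    return make
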