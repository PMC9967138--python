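"""Redness measurement: gamma correction, Otsu halo segmentation, masked R/G.

Flash photography of the gingiva often leaves near-saturated achromatic
"halo" reflections. Because white pixels have R/G = 1, they bias the mean
channel ratio of an inflamed (red, R/G well above 1) region toward 1. The
pipeline here removes them before averaging:

1. scale the 8-bit ROI to [0, 1];
2. gamma-correct (``C_out = b * C_in**gamma``, defaults b=1, gamma=2.2),
   which compresses mid-tones and leaves near-saturated values close to 1,
   accentuating the halo;
3. collapse to Rec.601 luminance and threshold with Otsu's method — the
   brighter class is the candidate halo (index map L; Linv is its complement);
4. average each raw 0-255 channel over the retained (Linv) pixels and report
   R/G = mean_R / mean_G.

Otsu always produces a split, even in halo-free regions, so a saturation
guard (default 0.85 on the gamma-corrected unit scale) only accepts the halo
class when it is actually bright; ``force_otsu=True`` disables the guard and
masks the brighter class unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AllHaloError, ParameterError, RatioUndefinedError
from .io import Photo, RgbRoi, RoiSpec, extract_roi

#: Rec.601 luma weights for (R, G, B).
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

DEFAULT_SAT_GUARD = 0.85


@dataclass(frozen=True)
class GammaParams:
    """Gain ``b`` and exponent ``gamma`` of the power-law intensity transform.

    Defaults b=1.0, gamma=2.2; both dimensionless and strictly positive.
    """

    b: float = 1.0
    gamma: float = 2.2

    def __post_init__(self):
        if not (self.b > 0):
            raise ParameterError(f"gamma gain b must be > 0, got {self.b}")
        if not (self.gamma > 0):
            raise ParameterError(f"gamma exponent must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class HaloMask:
    """Complementary index maps over an ROI.

    ``L`` marks halo-artifact pixels (1 = artifact), ``Linv`` the retained
    pixels; L + Linv = 1 everywhere. ``otsu_threshold`` is on the
    gamma-corrected unit luminance scale. ``halo_applied`` is False when the
    saturation guard rejected the split (or the ROI was degenerate), in which
    case every pixel is retained.
    """

    L: np.ndarray
    Linv: np.ndarray
    otsu_threshold: float
    halo_applied: bool

    def __post_init__(self):
        if self.L.shape != self.Linv.shape:
            raise ParameterError("L and Linv must have identical shape")
        if not np.array_equal(self.L + self.Linv, np.ones_like(self.L)):
            raise ParameterError("L and Linv must be complementary binary maps")


@dataclass(frozen=True)
class RednessResult:
    """Masked channel means (0-255 scale) and the R/G ratio of one ROI."""

    mean_r: float
    mean_g: float
    mean_b: float
    rg_ratio: float
    retained_pixels: int
    total_pixels: int
    halo_applied: bool
    otsu_threshold: float
    spec: RoiSpec | None = None

    @property
    def retained_fraction(self) -> float:
        return self.retained_pixels / self.total_pixels


def normalize(pixels: np.ndarray | RgbRoi) -> np.ndarray:
    """Scale 8-bit channel values to the unit interval (divide by 255)."""
    if isinstance(pixels, RgbRoi):
        pixels = pixels.pixels
    px = np.asarray(pixels)
    if px.size and (px.min() < 0 or px.max() > 255):
        raise ParameterError("channel values must lie in [0, 255]")
    return px.astype(np.float64) / 255.0


def gamma_correct(x: np.ndarray, params: GammaParams = GammaParams()) -> np.ndarray:
    """Apply ``b * x**gamma`` elementwise on unit-scaled data, clipped to [0, 1].

    Monotone non-decreasing in x for fixed parameters; with b=1 the end
    points 0 and 1 are fixed for any gamma, and gamma=1 is the identity.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.clip(params.b * np.power(x, params.gamma), 0.0, 1.0)


def luminance(x: np.ndarray) -> np.ndarray:
    """Rec.601 weighted sum 0.299 R + 0.587 G + 0.114 B of a unit-scaled raster."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ParameterError(f"expected a (H, W, 3) raster, got shape {x.shape}")
    return x @ LUMA_WEIGHTS


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's threshold of a unit-scaled raster on a ``bins``-bin histogram.

    Returns the bin center that maximizes the between-class variance; pixels
    strictly above the returned value belong to the brighter class. A
    constant raster has no split and returns the constant itself (callers
    must treat that case as degenerate). Ties take the lowest threshold.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ParameterError("cannot threshold an empty raster")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    mu0 = m / np.where(w0 == 0, 1.0, w0)
    mu1 = (m[-1] - m) / np.where(w1 == 0, 1.0, w1)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[-1] = -np.inf  # a cut after the last bin is no split
    idx = int(np.argmax(between))
    return float(centers[idx])


def segment_halo(
    roi: RgbRoi,
    params: GammaParams = GammaParams(),
    sat_guard: float = DEFAULT_SAT_GUARD,
    force_otsu: bool = False,
    cleanup: bool = False,
    bins: int = 256,
) -> HaloMask:
    """Segment near-saturated halo pixels out of an ROI.

    Pipeline: normalize → gamma_correct → luminance → otsu_threshold; pixels
    with gamma-corrected luminance above the threshold form the candidate
    halo class L. The split is accepted only if the candidate class's mean
    gamma-corrected luminance reaches ``sat_guard`` (or ``force_otsu`` is
    set); otherwise no pixel is masked. ``cleanup`` applies a binary opening
    to L to drop isolated single-pixel detections (off by default).
    """
    lum = luminance(gamma_correct(normalize(roi), params))
    thr = otsu_threshold(lum, bins=bins)
    shape = lum.shape
    if float(lum.min()) == float(lum.max()):
        L = np.zeros(shape, dtype=np.uint8)
        return HaloMask(L=L, Linv=1 - L, otsu_threshold=thr, halo_applied=False)
    candidate = lum > thr
    accepted = force_otsu or (
        candidate.any() and float(lum[candidate].mean()) >= sat_guard
    )
    if accepted and cleanup and candidate.any():
        candidate = ndimage.binary_opening(candidate)
    L = candidate.astype(np.uint8) if accepted else np.zeros(shape, dtype=np.uint8)
    return HaloMask(L=L, Linv=(1 - L).astype(np.uint8), otsu_threshold=thr,
                    halo_applied=bool(accepted and L.any()))


def masked_channel_means(roi: RgbRoi, mask: HaloMask) -> RednessResult:
    """Mean of each raw channel over retained pixels, and the R/G ratio.

    Implements the masked mean as sum(channel * Linv) / sum(Linv): masking
    zeroes artifact pixels, then the sum is divided by the retained count, so
    the result is the plain mean of the original 0-255 values over the
    retained set.
    """
    px = roi.pixels
    if mask.Linv.shape != px.shape[:2]:
        raise ParameterError(
            f"mask shape {mask.Linv.shape} does not match ROI {px.shape[:2]}"
        )
    n_keep = int(mask.Linv.sum())
    if n_keep == 0:
        raise AllHaloError(
            f"entire ROI flagged as halo ({roi.spec.photo_id}/{roi.spec.site})"
        )
    linv = mask.Linv.astype(np.float64)
    masked = px.astype(np.float64) * linv[:, :, None]
    means = masked.sum(axis=(0, 1)) / n_keep
    mean_r, mean_g, mean_b = (float(m) for m in means)
    if mean_g == 0:
        raise RatioUndefinedError(
            f"mean green intensity is zero ({roi.spec.photo_id}/{roi.spec.site})"
        )
    return RednessResult(
        mean_r=mean_r,
        mean_g=mean_g,
        mean_b=mean_b,
        rg_ratio=mean_r / mean_g,
        retained_pixels=n_keep,
        total_pixels=px.shape[0] * px.shape[1],
        halo_applied=mask.halo_applied,
        otsu_threshold=mask.otsu_threshold,
        spec=roi.spec,
    )


def measure_redness(
    photo: Photo,
    spec: RoiSpec,
    params: GammaParams = GammaParams(),
    sat_guard: float = DEFAULT_SAT_GUARD,
    force_otsu: bool = False,
    remove_halo: bool = True,
    cleanup: bool = False,
) -> RednessResult:
    """Full per-ROI measurement: crop, segment halo, masked channel means.

    ``remove_halo=False`` skips masking entirely (the naive estimate over all
    pixels), which is only useful for quantifying the halo bias.
    """
    roi = extract_roi(photo, spec)
    if remove_halo:
        mask = segment_halo(roi, params, sat_guard=sat_guard,
                            force_otsu=force_otsu, cleanup=cleanup)
    else:
        z = np.zeros(roi.pixels.shape[:2], dtype=np.uint8)
        mask = HaloMask(L=z, Linv=1 - z, otsu_threshold=0.0, halo_applied=False)
    return masked_channel_means(roi, mask)
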