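"""Synthetic gingiva images and longitudinal cohorts with known ground truth.

Clinical intra-oral photographs are not redistributable, so every other
module is exercised on generated data: gingiva-toned pixel patches with a
controllable true R/G ratio and Gaussian pixel noise, optional near-saturated
flash-halo disks with exact ground-truth masks, and subject x time-point x
site cohorts with a planted time effect and a monotone GI link.

The generator makes no attempt at photorealistic texture — the estimator
consumes only channel means, so i.i.d. 8-bit Gaussian noise with clipping is
sufficient to exercise it. All randomness flows from one explicit seed.

Defaults mirror the study conditions: 25 subjects, four time points
(BO/MO/TO/IDO), six papillary sites, population R/G means ordered
MO < BO < TO < IDO inside the clinically observed band [1.48, 1.88].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import ParameterError
from .gi import GIScore, write_gi_scores
from .io import SITES, SITE_JAW, TIMEPOINTS, Photo, RoiSpec, write_roi_manifest

#: Dimensions (width, height) of a typical clinical intra-oral photograph.
CLINICAL_PHOTO_SIZE = (5000, 3300)

#: Default per-time-point population R/G means: strict MO < BO < TO < IDO
#: ordering inside the observed cross-site band.
DEFAULT_TP_MEANS: dict[str, float] = {"BO": 1.62, "MO": 1.52, "TO": 1.66, "IDO": 1.76}

#: Per-site offsets around the time-point mean (anterior maxillary papillae
#: run redder laterally; mandibular incisor papillae slightly paler).
DEFAULT_SITE_OFFSETS: dict[str, float] = {
    "U_12_13": 0.08,
    "U_11_21": -0.07,
    "U_22_23": 0.15,
    "L_43_42": -0.04,
    "L_41_31": -0.07,
    "L_32_33": -0.03,
}

#: Monotone step link from true R/G to the ordinal GI 0-4.
DEFAULT_GI_CUTS: tuple[float, ...] = (1.52, 1.62, 1.72, 1.82)


@dataclass(frozen=True)
class HaloSpec:
    """A flash-halo disk: center (cx, cy) in pixels, radius, 8-bit level."""

    cx: float
    cy: float
    radius: float
    level: int = 255

    def __post_init__(self):
        if self.level < 250:
            raise ParameterError(f"halo level must be >= 250 (near saturation), got {self.level}")
        if self.radius <= 0:
            raise ParameterError("halo radius must be positive")


@dataclass(frozen=True)
class RoiGroundTruth:
    """Ground truth for one generated ROI patch."""

    true_rg: float
    base_g: int = 100
    base_b: int = 90
    noise_sd: float = 4.0
    halo: HaloSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.true_rg * self.base_g > 255:
            raise ParameterError(
                f"infeasible red level {self.true_rg * self.base_g:.1f} > 255"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticRoi:
    """A generated patch plus everything a test needs to check against it."""

    photo: Photo
    spec: RoiSpec
    truth: RoiGroundTruth
    halo_mask: np.ndarray  # ground-truth boolean mask (>= 50% disk coverage)

    @property
    def halo_fraction(self) -> float:
        return float(self.halo_mask.mean())


def halo_radius_for_fraction(fraction: float, width: int, height: int) -> float:
    """Disk radius whose area is ``fraction`` of a width x height patch."""
    if not (0 < fraction < 0.5):
        raise ParameterError("halo area fraction must be in (0, 0.5)")
    return math.sqrt(fraction * width * height / math.pi)


def generate_roi(
    gt: RoiGroundTruth,
    width: int = 96,
    height: int = 96,
    site: str = "U_11_21",
    timepoint: str = "BO",
    photo_id: str | None = None,
    subject_id: str = "",
) -> SyntheticRoi:
    """Render one gingiva-toned patch with Gaussian pixel noise.

    Channel means of the noise-free base are exactly
    (true_rg * base_g, base_g, base_b). The optional halo disk is drawn with
    a 1-pixel anti-aliased soft edge at near saturation; the returned
    ground-truth mask uses the >= 50%-coverage rule (distance <= radius).
    Reproducible for a fixed ``gt.seed``.
    """
    rng = np.random.default_rng(gt.seed)
    base = np.array([gt.true_rg * gt.base_g, gt.base_g, gt.base_b], dtype=np.float64)
    img = np.broadcast_to(base, (height, width, 3)).copy()
    if gt.noise_sd > 0:
        img += rng.normal(0.0, gt.noise_sd, size=img.shape)
    halo_mask = np.zeros((height, width), dtype=bool)
    if gt.halo is not None:
        yy, xx = np.mgrid[0:height, 0:width]
        dist = np.hypot(xx - gt.halo.cx, yy - gt.halo.cy)
        alpha = np.clip(gt.halo.radius + 0.5 - dist, 0.0, 1.0)
        img = alpha[:, :, None] * float(gt.halo.level) + (1 - alpha[:, :, None]) * img
        halo_mask = dist <= gt.halo.radius
        if halo_mask.mean() >= 0.5:
            raise ParameterError("halo covers >= 50% of the patch")
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pid = photo_id or f"synth_{gt.seed}"
    photo = Photo(photo_id=pid, pixels=pixels)
    spec = RoiSpec(photo_id=pid, site=site, timepoint=timepoint,
                   rect=(0, 0, width, height), subject_id=subject_id)
    return SyntheticRoi(photo=photo, spec=spec, truth=gt, halo_mask=halo_mask)


@dataclass(frozen=True)
class CohortGroundTruth:
    """Population parameters of a generated longitudinal cohort."""

    n_subjects: int = 25
    tp_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TP_MEANS))
    site_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_OFFSETS))
    between_sd: float = 0.06
    within_sd: float = 0.03
    base_g: int = 100
    base_b: int = 90
    noise_sd: float = 4.0
    halo_prob: float = 0.3
    halo_frac_range: tuple[float, float] = (0.04, 0.12)
    gi_cuts: tuple[float, ...] = DEFAULT_GI_CUTS
    gi_noise_p: float = 0.15
    patch_size: int = 80
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if any(m <= 0 for m in self.tp_means.values()):
            raise ParameterError("population R/G means must be positive")
        if sorted(self.tp_means) != sorted(TIMEPOINTS):
            raise ParameterError(f"tp_means must cover exactly {TIMEPOINTS}")


def gi_from_rg(rg: float, cuts: tuple[float, ...] = DEFAULT_GI_CUTS) -> int:
    """Monotone step link: number of cut points the R/G value exceeds (0-4)."""
    return int(sum(rg > c for c in cuts))


@dataclass(frozen=True)
class CohortData:
    """A generated cohort: photos, manifest, GI scores and the planted truth."""

    photos: dict[str, Photo]
    manifest: list[RoiSpec]
    gi_scores: list[GIScore]
    truth: pd.DataFrame  # per-ROI planted values
    ground_truth: CohortGroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Persist as PNG images + manifest CSV + GI CSV + truth CSV."""
        out = Path(out_dir)
        images = out / "images"
        images.mkdir(parents=True, exist_ok=True)
        for pid, photo in self.photos.items():
            iio.imwrite(images / f"{pid}.png", photo.pixels)
        paths = {
            "images": images,
            "manifest": out / "manifest.csv",
            "gi": out / "gi_scores.csv",
            "truth": out / "truth.csv",
        }
        write_roi_manifest(self.manifest, paths["manifest"])
        write_gi_scores(self.gi_scores, paths["gi"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def generate_cohort(gt: CohortGroundTruth = CohortGroundTruth()) -> CohortData:
    """Generate a full longitudinal cohort with planted effects.

    One photo per subject x time point, holding the six papillary-site
    patches in a 3 x 2 grid; per-site true R/G = time-point mean + site
    offset + subject effect + within-site noise, clipped to the feasible
    8-bit band. GI scores follow the monotone step link with ordinal noise
    (+/- 1 with probability ``gi_noise_p``).
    """
    rng = np.random.default_rng(gt.seed)
    ps = gt.patch_size
    photos: dict[str, Photo] = {}
    manifest: list[RoiSpec] = []
    scores: list[GIScore] = []
    truth_rows: list[dict] = []
    rg_cap = (255.0 - 4.0 * gt.noise_sd) / gt.base_g
    for s in range(gt.n_subjects):
        subject_id = f"S{s + 1:02d}"
        subj_eff = rng.normal(0.0, gt.between_sd)
        for tp in TIMEPOINTS:
            photo_id = f"{subject_id}_{tp}"
            canvas = np.zeros((2 * ps, 3 * ps, 3), dtype=np.uint8)
            for i, site in enumerate(SITES):
                col, row = i % 3, i // 3
                true_rg = float(np.clip(
                    gt.tp_means[tp] + gt.site_offsets[site]
                    + subj_eff + rng.normal(0.0, gt.within_sd),
                    1.05, min(2.3, rg_cap),
                ))
                halo = None
                if rng.random() < gt.halo_prob:
                    frac = rng.uniform(*gt.halo_frac_range)
                    radius = halo_radius_for_fraction(frac, ps, ps)
                    margin = radius + 1.0
                    halo = HaloSpec(
                        cx=rng.uniform(margin, ps - margin),
                        cy=rng.uniform(margin, ps - margin),
                        radius=radius,
                        level=int(rng.integers(252, 256)),
                    )
                roi_seed = int(rng.integers(0, 2**31 - 1))
                roi = generate_roi(
                    RoiGroundTruth(true_rg=true_rg, base_g=gt.base_g, base_b=gt.base_b,
                                   noise_sd=gt.noise_sd, halo=halo, seed=roi_seed),
                    width=ps, height=ps, site=site, timepoint=tp,
                    photo_id=photo_id, subject_id=subject_id,
                )
                x0, y0 = col * ps, row * ps
                canvas[y0:y0 + ps, x0:x0 + ps, :] = roi.photo.pixels
                manifest.append(RoiSpec(photo_id=photo_id, site=site, timepoint=tp,
                                        rect=(x0, y0, x0 + ps, y0 + ps),
                                        subject_id=subject_id))
                gi = gi_from_rg(true_rg, gt.gi_cuts)
                if rng.random() < gt.gi_noise_p:
                    gi = int(np.clip(gi + rng.choice([-1, 1]), 0, 4))
                scores.append(GIScore(subject_id=subject_id, site=site,
                                      timepoint=tp, score=gi))
                truth_rows.append({
                    "subject_id": subject_id, "photo_id": photo_id, "site": site,
                    "jaw": SITE_JAW[site], "timepoint": tp, "true_rg": true_rg,
                    "gi": gi, "halo_fraction": roi.halo_fraction,
                })
            photos[photo_id] = Photo(photo_id=photo_id, pixels=canvas)
    return CohortData(photos=photos, manifest=manifest, gi_scores=scores,
                      truth=pd.DataFrame(truth_rows), ground_truth=gt)


def generate_study_fixture(seed: int = 0, **kwargs) -> CohortData:
    """The study-scale fixture: 98 photos x 6 sites = 588 ROI records.

    A 25-subject x 4-time-point cohort yields 100 photos; the study kept 98
    after photo quality control, so the last two photos (one subject's TO and
    IDO visits) are removed here, together with their manifest rows, GI
    scores and truth rows.
    """
    gt = CohortGroundTruth(n_subjects=25, seed=seed, **kwargs)
    cohort = generate_cohort(gt)
    drop_subject, drop_tps = f"S{gt.n_subjects:02d}", ("TO", "IDO")
    dropped = {f"{drop_subject}_{tp}" for tp in drop_tps}
    photos = {k: v for k, v in cohort.photos.items() if k not in dropped}
    manifest = [m for m in cohort.manifest if m.photo_id not in dropped]
    scores = [s for s in cohort.gi_scores
              if not (s.subject_id == drop_subject and s.timepoint in drop_tps)]
    truth = cohort.truth[~cohort.truth["photo_id"].isin(dropped)].reset_index(drop=True)
    return CohortData(photos=photos, manifest=manifest, gi_scores=scores,
                      truth=truth, ground_truth=gt)


def _binned_spearman(latent_r: float, n_levels: int = 5) -> float:
    """Population Spearman between X and Y binned into equal quantile levels,
    for (X, Y) standard bivariate normal with Pearson correlation latent_r.

    Uses midrank grades for the tied (binned) margin: the grade of level j is
    the midpoint of its probability interval. E[Phi(X) 1{Y <= c}] equals the
    bivariate normal orthant probability P(X' - X <= 0, Y <= c) with
    corr(X' - X, Y) = -latent_r / sqrt(2).
    """
    probs = np.arange(1, n_levels) / n_levels
    cuts = sps.norm.ppf(probs)
    rho12 = -latent_r / math.sqrt(2.0)
    cov = np.array([[1.0, rho12], [rho12, 1.0]])

    def e_phi_below(c: float) -> float:
        return float(sps.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([0.0, c]))

    cdf_vals = [0.0] + [e_phi_below(c) for c in cuts] + [0.5]  # E[Phi(X)] = 1/2
    p_cum = np.concatenate([[0.0], probs, [1.0]])
    e_uv = 0.0
    for j in range(n_levels):
        grade = (p_cum[j] + p_cum[j + 1]) / 2.0
        e_uv += grade * (cdf_vals[j + 1] - cdf_vals[j])
    var_u = 1.0 / 12.0
    grades = (p_cum[:-1] + p_cum[1:]) / 2.0
    pj = np.diff(p_cum)
    var_v = float((pj * grades**2).sum() - 0.25)
    return (e_uv - 0.25) / math.sqrt(var_u * var_v)


def calibrate_latent_correlation(target_rho: float, n_levels: int = 5) -> float:
    """Latent Gaussian-copula Pearson r whose post-binning Spearman hits target.

    Binning the GI margin into ordinal levels attenuates rank correlation;
    this inverts the attenuation so the *planted* (post-binning) population
    Spearman equals the requested link strength.
    """
    if not (0 < target_rho < 0.97):
        raise ParameterError("target Spearman must be in (0, 0.97)")
    f = lambda r: _binned_spearman(r, n_levels) - target_rho
    return float(optimize.brentq(f, 1e-6, 0.9999, xtol=1e-6))


def generate_linked_reduced_table(
    n_subjects: int = 100,
    link_rho: float = 0.8,
    seed: int = 0,
    tp_means: dict[str, float] | None = None,
    rg_sd: float = 0.15,
) -> pd.DataFrame:
    """A reduced-level table (subject x jaw x timepoint) with a planted GI link.

    For every (jaw, timepoint) cell, the highest-R/G and highest-GI values
    are drawn from a Gaussian copula calibrated so the population Spearman
    between R/G and the ordinal (0-4) GI equals ``link_rho``. Suitable as
    direct input to the GI x R/G correlation analysis.
    """
    tp_means = tp_means or dict(DEFAULT_TP_MEANS)
    latent_r = calibrate_latent_correlation(link_rho)
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, latent_r], [latent_r, 1.0]])
    gi_cuts = sps.norm.ppf(np.arange(1, 5) / 5)  # equal quintile levels
    rows = []
    for jaw in ("maxilla", "mandible"):
        for tp in TIMEPOINTS:
            z = rng.multivariate_normal([0.0, 0.0], cov, size=n_subjects)
            rg = tp_means[tp] + rg_sd * z[:, 0]
            gi = np.searchsorted(gi_cuts, z[:, 1])
            for s in range(n_subjects):
                rows.append({
                    "subject_id": f"S{s + 1:03d}", "jaw": jaw, "timepoint": tp,
                    "rg_ratio": float(rg[s]), "gi": int(gi[s]),
                })
    return pd.DataFrame(rows)
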