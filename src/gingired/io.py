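"""Photographs, ROI manifests and result tables.

The study vocabulary lives here: six papillary-gingiva sites on the anterior
teeth (FDI tooth-pair labels, three maxillary and three mandibular) and four
orthodontic time points (BO = before treatment, MO = mid-point, TO =
three-quarters through, IDO = immediately after debonding).

Coordinates are 0-based and half-open: a rect ``(x0, y0, x1, y1)`` selects
columns ``x0 <= x < x1`` and rows ``y0 <= y < y1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, ManifestError

logger = logging.getLogger(__name__)

#: Papillary-gingiva site labels, maxilla first. ``U_12_13`` is the papilla
#: between teeth #12 and #13, etc.
SITES: tuple[str, ...] = (
    "U_12_13",
    "U_11_21",
    "U_22_23",
    "L_43_42",
    "L_41_31",
    "L_32_33",
)

TIMEPOINTS: tuple[str, ...] = ("BO", "MO", "TO", "IDO")

SITE_JAW: dict[str, str] = {s: ("maxilla" if s.startswith("U_") else "mandible") for s in SITES}

JAW_SITES: dict[str, tuple[str, ...]] = {
    "maxilla": tuple(s for s in SITES if SITE_JAW[s] == "maxilla"),
    "mandible": tuple(s for s in SITES if SITE_JAW[s] == "mandible"),
}

#: Fixed column order of the results CSV.
RESULT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "photo_id",
    "site",
    "jaw",
    "timepoint",
    "rg_ratio",
    "mean_r",
    "mean_g",
    "mean_b",
    "retained_pixel_fraction",
    "gi",
)

MANIFEST_COLUMNS: tuple[str, ...] = (
    "photo_id",
    "site",
    "timepoint",
    "x0",
    "y0",
    "x1",
    "y1",
    "subject_id",
)


@dataclass(frozen=True)
class Photo:
    """An 8-bit three-channel raster with an identity.

    ``pixels`` has shape (height, width, 3), dtype uint8.
    """

    photo_id: str
    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"photo {self.photo_id!r}: expected a (H, W, 3) raster, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise FormatError(
                f"photo {self.photo_id!r}: expected 8-bit channels, got dtype {px.dtype}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"photo {self.photo_id!r}: empty raster")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiSpec:
    """A named rectangular papillary-gingiva region within one photo."""

    photo_id: str
    site: str
    timepoint: str
    rect: tuple[int, int, int, int]
    subject_id: str = ""

    def __post_init__(self):
        if self.site not in SITES:
            raise ManifestError(f"unknown site label {self.site!r}", field="site")
        if self.timepoint not in TIMEPOINTS:
            raise ManifestError(f"unknown timepoint label {self.timepoint!r}", field="timepoint")
        x0, y0, x1, y1 = (int(v) for v in self.rect)
        if not (0 <= x0 < x1):
            raise ManifestError(f"rect requires 0 <= x0 < x1, got x0={x0}, x1={x1}", field="rect")
        if not (0 <= y0 < y1):
            raise ManifestError(f"rect requires 0 <= y0 < y1, got y0={y0}, y1={y1}", field="rect")
        object.__setattr__(self, "rect", (x0, y0, x1, y1))

    @property
    def jaw(self) -> str:
        return SITE_JAW[self.site]

    @property
    def width(self) -> int:
        return self.rect[2] - self.rect[0]

    @property
    def height(self) -> int:
        return self.rect[3] - self.rect[1]


@dataclass(frozen=True)
class RgbRoi:
    """A cropped ROI raster together with the spec that produced it."""

    pixels: np.ndarray
    spec: RoiSpec

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise FormatError(f"ROI raster must be (H, W, 3) uint8, got {px.shape} {px.dtype}")
        if px.shape[0] != self.spec.height or px.shape[1] != self.spec.width:
            raise BoundsError(
                f"ROI raster {px.shape[1]}x{px.shape[0]} does not match rect "
                f"{self.spec.width}x{self.spec.height}"
            )
        object.__setattr__(self, "pixels", px)


def read_photo(path: str | Path, photo_id: str | None = None) -> Photo:
    """Read a JPEG or PNG photograph as an 8-bit RGB :class:`Photo`.

    Grayscale inputs are rejected; an alpha channel is dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"photo file not found: {path}")
    try:
        px = iio.imread(path)
    except Exception as exc:  # decoder failures vary by backend
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if px.ndim == 2 or (px.ndim == 3 and px.shape[2] == 1):
        raise FormatError(f"{path}: single-channel image; 3-channel RGB required")
    if px.ndim != 3 or px.shape[2] not in (3, 4):
        raise FormatError(f"{path}: unsupported raster shape {px.shape}")
    if px.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", path)
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit channels, got {px.dtype}")
    return Photo(photo_id=photo_id or path.stem, pixels=px)


def _validate_manifest_row(row: dict, idx: int) -> RoiSpec:
    for col in MANIFEST_COLUMNS[:-1]:  # subject_id optional
        if col not in row or row[col] is None or (isinstance(row[col], float) and np.isnan(row[col])):
            raise ManifestError("missing value", row=idx, field=col)
    try:
        rect = tuple(int(row[c]) for c in ("x0", "y0", "x1", "y1"))
    except (TypeError, ValueError) as exc:
        raise ManifestError(f"non-integer rect coordinate: {exc}", row=idx) from exc
    try:
        return RoiSpec(
            photo_id=str(row["photo_id"]),
            site=str(row["site"]),
            timepoint=str(row["timepoint"]),
            rect=rect,
            subject_id="" if pd.isna(row.get("subject_id", "")) else str(row.get("subject_id", "")),
        )
    except ManifestError as exc:
        raise ManifestError(str(exc), row=idx) from exc


def read_roi_manifest(path: str | Path) -> list[RoiSpec]:
    """Read an ROI manifest (JSON list of objects, or CSV).

    Columns/keys: photo_id, site, timepoint, x0, y0, x1, y1, subject_id.
    Site and time-point labels must be from the study vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    if path.suffix.lower() == ".json":
        text = path.read_text().strip()
        records = json.loads(text) if text else []
        if not isinstance(records, list):
            raise ManifestError("JSON manifest must be a list of objects")
    else:
        if path.stat().st_size == 0:
            return []
        df = pd.read_csv(path)
        if df.empty:
            return []
        records = df.to_dict("records")
    return [_validate_manifest_row(rec, i) for i, rec in enumerate(records)]


def write_roi_manifest(specs: list[RoiSpec], path: str | Path) -> None:
    """Write specs as a manifest CSV in the documented column order."""
    rows = [
        {
            "photo_id": s.photo_id,
            "site": s.site,
            "timepoint": s.timepoint,
            "x0": s.rect[0],
            "y0": s.rect[1],
            "x1": s.rect[2],
            "y1": s.rect[3],
            "subject_id": s.subject_id,
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


def extract_roi(photo: Photo, spec: RoiSpec) -> RgbRoi:
    """Crop the spec's rectangle out of the photo, channels preserved."""
    x0, y0, x1, y1 = spec.rect
    if x1 > photo.width or y1 > photo.height:
        raise BoundsError(
            f"rect {spec.rect} exceeds photo {photo.photo_id!r} "
            f"({photo.width}x{photo.height})"
        )
    return RgbRoi(pixels=photo.pixels[y0:y1, x0:x1, :].copy(), spec=spec)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check CohortTable invariants: key uniqueness and positive R/G."""
    for col in ("subject_id", "site", "jaw", "timepoint", "rg_ratio"):
        if col not in table.columns:
            raise ManifestError(f"cohort table missing column {col!r}", field=col)
    key = table[["subject_id", "site", "timepoint"]]
    dup = key.duplicated()
    if dup.any():
        first = table[dup].iloc[0]
        raise ManifestError(
            "duplicate (subject, site, timepoint): "
            f"({first['subject_id']}, {first['site']}, {first['timepoint']})"
        )
    rg = table["rg_ratio"].dropna()
    if (rg <= 0).any():
        raise ManifestError("rg_ratio must be positive where present", field="rg_ratio")
    bad_site = ~table["site"].isin(SITES)
    if bad_site.any():
        raise ManifestError(f"unknown site {table.loc[bad_site, 'site'].iloc[0]!r}", field="site")
    bad_tp = ~table["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        raise ManifestError(
            f"unknown timepoint {table.loc[bad_tp, 'timepoint'].iloc[0]!r}", field="timepoint"
        )
    return table


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a CohortTable as CSV: fixed column order, floats at 6 decimals."""
    out = table.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[list(RESULT_COLUMNS)]
    out.to_csv(path, index=False, float_format="%.6f")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"subject_id": str, "photo_id": str})
    return df
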