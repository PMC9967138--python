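"""Batch pipeline: measure every manifest ROI, join GI scores, run the stats."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .errors import GingiredError, ParameterError
from .gi import read_gi_scores
from .redness import DEFAULT_SAT_GUARD, GammaParams, measure_redness
from .stats import gi_rg_correlation_matrix, longitudinal_summary, max_site_per_jaw

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".PNG", ".JPG", ".JPEG")


@dataclass
class RunConfig:
    """Everything one batch run needs.

    ``alpha`` is the significance level (default 0.05); ``seed`` feeds any
    Monte-Carlo permutation p-values.
    """

    images_dir: Path
    manifest: Path
    out_dir: Path
    gi_scores: Path | None = None
    gamma: GammaParams = field(default_factory=GammaParams)
    sat_guard: float = DEFAULT_SAT_GUARD
    force_otsu: bool = False
    exact_perm: bool = False
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.images_dir = Path(self.images_dir)
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if self.gi_scores is not None:
            self.gi_scores = Path(self.gi_scores)
        if not (0 < self.alpha < 1):
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")


def _find_image(images_dir: Path, photo_id: str) -> Path:
    for suf in IMAGE_SUFFIXES:
        p = images_dir / f"{photo_id}{suf}"
        if p.exists():
            return p
    raise IOError(f"no image file for photo_id {photo_id!r} in {images_dir}")


@dataclass
class MeasureReport:
    n_rois: int
    n_ok: int
    failures: list[dict]

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def run_measure(config: RunConfig) -> tuple[pd.DataFrame, MeasureReport]:
    """Measure every ROI in the manifest; per-ROI failures do not abort the run.

    Returns the long-format results table (one row per ROI that measured
    successfully) and a report reconciling rows in = rows out + failures.
    """
    if not config.manifest.exists():
        raise IOError(f"manifest not found: {config.manifest}")
    specs = gio.read_roi_manifest(config.manifest)
    photo_cache: dict[str, gio.Photo] = {}
    rows: list[dict] = []
    failures: list[dict] = []
    for spec in specs:
        try:
            if spec.photo_id not in photo_cache:
                photo_cache[spec.photo_id] = gio.read_photo(
                    _find_image(config.images_dir, spec.photo_id), photo_id=spec.photo_id
                )
            res = measure_redness(
                photo_cache[spec.photo_id], spec, params=config.gamma,
                sat_guard=config.sat_guard, force_otsu=config.force_otsu,
            )
        except (GingiredError, IOError) as exc:
            logger.error("ROI %s/%s/%s failed: %s", spec.photo_id, spec.site,
                         spec.timepoint, exc)
            failures.append({"photo_id": spec.photo_id, "site": spec.site,
                             "timepoint": spec.timepoint, "error": str(exc)})
            continue
        rows.append({
            "subject_id": spec.subject_id, "photo_id": spec.photo_id,
            "site": spec.site, "jaw": spec.jaw, "timepoint": spec.timepoint,
            "rg_ratio": res.rg_ratio, "mean_r": res.mean_r, "mean_g": res.mean_g,
            "mean_b": res.mean_b, "retained_pixel_fraction": res.retained_fraction,
            "gi": np.nan,
        })
    table = pd.DataFrame(rows, columns=list(gio.RESULT_COLUMNS))
    report = MeasureReport(n_rois=len(specs), n_ok=len(rows), failures=failures)
    logger.info("measured %d/%d ROIs (%d failed)", report.n_ok, report.n_rois,
                report.n_failed)
    return table, report


def join_gi(table: pd.DataFrame, gi_path: Path) -> pd.DataFrame:
    """Left-join GI scores onto the results table by (subject, site, timepoint)."""
    scores = read_gi_scores(gi_path)
    gi_df = pd.DataFrame(
        [{"subject_id": s.subject_id, "site": s.site, "timepoint": s.timepoint,
          "gi": s.score} for s in scores]
    )
    out = table.drop(columns=["gi"]).merge(
        gi_df, on=["subject_id", "site", "timepoint"], how="left"
    )
    return out[list(gio.RESULT_COLUMNS)]


def run_stats(config: RunConfig, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Longitudinal summaries and the per-jaw GI x R/G correlation matrix.

    Emits the R/G longitudinal table always; the GI longitudinal table and
    the correlation matrix only when GI scores are present (otherwise skipped
    with a notice). An analysis that fails for lack of data is skipped while
    the others are still produced.
    """
    out: dict[str, pd.DataFrame] = {}
    out["longitudinal_rg"] = longitudinal_summary(
        table, value="rg_ratio", exact=config.exact_perm, seed=config.seed
    )
    has_gi = "gi" in table.columns and table["gi"].notna().any()
    if not has_gi:
        logger.info("no GI scores present; GI analyses skipped")
        return out
    try:
        out["longitudinal_gi"] = longitudinal_summary(
            table.dropna(subset=["gi"]), value="gi",
            exact=config.exact_perm, seed=config.seed,
        )
    except GingiredError as exc:
        logger.warning("GI longitudinal summary skipped: %s", exc)
    try:
        reduced = max_site_per_jaw(table.dropna(subset=["gi"]))
        out["max_site_reduced"] = reduced
        out["gi_rg_correlation"] = gi_rg_correlation_matrix(reduced)
    except GingiredError as exc:
        logger.warning("GI x R/G correlation skipped: %s", exc)
    return out


def write_stats_outputs(outputs: dict[str, pd.DataFrame], out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in outputs.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        written.append(p)
    return written
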