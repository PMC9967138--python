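"""Reusable validation experiments on synthetic data.

Each function generates its own inputs from an explicit seed, runs the
package's estimators, and returns summary numbers. They back both the test
suite and the reproduction script, so the quantities are always recomputed
from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TIMEPOINTS, read_roi_manifest
from .pipeline import RunConfig, run_measure
from .redness import measure_redness
from .stats import friedman_test, gi_rg_correlation_matrix, longitudinal_summary
from .synthetic import (
    CohortGroundTruth,
    HaloSpec,
    RoiGroundTruth,
    generate_cohort,
    generate_linked_reduced_table,
    generate_roi,
    generate_study_fixture,
    halo_radius_for_fraction,
)


@dataclass(frozen=True)
class HaloRecoveryResult:
    masked_mae: float
    naive_mae: float
    paired_mean_diff: float  # mean(naive_err - masked_err); positive = masking helps
    n_rois: int


def halo_recovery_experiment(
    n_rois: int = 200,
    seed: int = 0,
    rg_range: tuple[float, float] = (1.4, 1.9),
    halo_frac_range: tuple[float, float] = (0.05, 0.20),
    size: int = 96,
    noise_sd: float = 4.0,
) -> HaloRecoveryResult:
    """Paired comparison of masked vs naive R/G over halo-bearing ROIs.

    True R/G is drawn uniformly in the clinically observed band; each ROI
    carries one saturated halo disk covering the given area fraction range.
    The masked estimate uses the default pipeline; the naive estimate
    averages over all pixels.
    """
    rng = np.random.default_rng(seed)
    masked_err, naive_err = [], []
    for i in range(n_rois):
        true_rg = rng.uniform(*rg_range)
        frac = rng.uniform(*halo_frac_range)
        radius = halo_radius_for_fraction(frac, size, size)
        margin = radius + 1.5
        halo = HaloSpec(cx=rng.uniform(margin, size - margin),
                        cy=rng.uniform(margin, size - margin),
                        radius=radius, level=255)
        roi = generate_roi(
            RoiGroundTruth(true_rg=true_rg, noise_sd=noise_sd, halo=halo,
                           seed=int(rng.integers(0, 2**31 - 1))),
            width=size, height=size,
        )
        masked = measure_redness(roi.photo, roi.spec).rg_ratio
        naive = measure_redness(roi.photo, roi.spec, remove_halo=False).rg_ratio
        masked_err.append(abs(masked - true_rg))
        naive_err.append(abs(naive - true_rg))
    masked_err = np.array(masked_err)
    naive_err = np.array(naive_err)
    return HaloRecoveryResult(
        masked_mae=float(masked_err.mean()),
        naive_mae=float(naive_err.mean()),
        paired_mean_diff=float((naive_err - masked_err).mean()),
        n_rois=n_rois,
    )


def friedman_type1_rate(
    n: int = 25,
    k: int = 4,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the chi-square Friedman test under the null.

    Independent standard-normal values in every cell; should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=(n, k))
        rejections += friedman_test(x).p_value <= alpha
    return rejections / reps


@dataclass(frozen=True)
class CohortRecoveryResult:
    max_friedman_p: float
    ordering_recovered: bool
    recovered_order: tuple[str, ...]  # time points sorted by cross-site mean R/G
    mae_vs_truth: float
    n_rows: int


def planted_cohort_recovery(n_subjects: int = 25, seed: int = 0) -> CohortRecoveryResult:
    """Generate a cohort, measure every ROI, and test the planted time effect.

    Recovers the per-site longitudinal summary; the planted population
    ordering of time-point means is MO < BO < TO < IDO.
    """
    cohort = generate_cohort(CohortGroundTruth(n_subjects=n_subjects, seed=seed))
    rows = []
    for spec in cohort.manifest:
        res = measure_redness(cohort.photos[spec.photo_id], spec)
        rows.append({"subject_id": spec.subject_id, "site": spec.site,
                     "jaw": spec.jaw, "timepoint": spec.timepoint,
                     "rg_ratio": res.rg_ratio})
    table = pd.DataFrame(rows)
    summ = longitudinal_summary(table)
    grand_means = {tp: float(summ[f"mean_{tp}"].mean()) for tp in TIMEPOINTS}
    order = tuple(sorted(grand_means, key=grand_means.get))
    mae = float(
        table.merge(cohort.truth, on=["subject_id", "site", "timepoint"])
        .eval("abs(rg_ratio - true_rg)").mean()
    )
    return CohortRecoveryResult(
        max_friedman_p=float(summ["p_value"].max()),
        ordering_recovered=order == ("MO", "BO", "TO", "IDO"),
        recovered_order=order,
        mae_vs_truth=mae,
        n_rows=len(table),
    )


@dataclass(frozen=True)
class LinkRecoveryResult:
    target_rho: float
    cell_rhos: pd.DataFrame
    max_abs_deviation: float


def linked_correlation_recovery(
    n_subjects: int = 100,
    link_rho: float = 0.8,
    seed: int = 0,
) -> LinkRecoveryResult:
    """Recover a planted GI-R/G Spearman link in every jaw x time-point cell."""
    reduced = generate_linked_reduced_table(n_subjects=n_subjects,
                                            link_rho=link_rho, seed=seed)
    mat = gi_rg_correlation_matrix(reduced)
    dev = float((mat["rho"] - link_rho).abs().max())
    return LinkRecoveryResult(target_rho=link_rho, cell_rhos=mat,
                              max_abs_deviation=dev)


@dataclass(frozen=True)
class RoiAccountingResult:
    n_photos: int
    n_specs: int
    n_measured: int
    n_failed: int


def study_roi_accounting(workdir: str | Path, seed: int = 0) -> RoiAccountingResult:
    """Write the study-scale fixture to disk, read it back, measure every ROI.

    Exercises the full file-based path: PNG images, manifest CSV validation,
    and the batch measurement loop.
    """
    workdir = Path(workdir)
    cohort = generate_study_fixture(seed=seed)
    paths = cohort.write(workdir)
    specs = read_roi_manifest(paths["manifest"])
    cfg = RunConfig(images_dir=paths["images"], manifest=paths["manifest"],
                    out_dir=workdir / "out", seed=seed)
    table, report = run_measure(cfg)
    return RoiAccountingResult(n_photos=len(cohort.photos), n_specs=len(specs),
                               n_measured=len(table), n_failed=report.n_failed)
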