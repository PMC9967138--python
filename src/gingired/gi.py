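"""Modified gingival index (GI): rubric, score validation, rater concordance.

The modified GI is an ordinal 0-4 visual score of gingival inflammation
(color, texture, edema, extent of the involved gingival unit). Scoring is a
human visual task: this module stores and audits scores, it never infers
them from pixels — keeping GI and the image-derived R/G ratio statistically
independent measurements of the same lesion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ScoreValidationError
from .io import SITES, TIMEPOINTS


@dataclass(frozen=True)
class RubricRow:
    score: int
    diagnosis: str
    criteria: str
    color: str
    texture: str
    volume: str
    extent: str


#: The five-level modified gingival index rubric.
GI_RUBRIC: tuple[RubricRow, ...] = (
    RubricRow(0, "Healthy", "Absence of inflammation",
              "Normal", "Normal", "Normal", "None"),
    RubricRow(1, "Mild inflammation (partial unit)",
              "Slight change in color, a little change in the texture of any "
              "portion of, but not the entire, marginal or papillary gingival unit",
              "Slightly more reddish or bluish-reddish", "Slightly glazy",
              "Slight edema of the margin", "Part of the gingival unit"),
    RubricRow(2, "Mild inflammation (entire unit)",
              "Criteria as above but involving the entire marginal or papillary "
              "gingival unit",
              "Slightly more reddish or bluish-reddish", "Slightly glazy",
              "Slight edema of the margin", "Entire gingival unit"),
    RubricRow(3, "Moderate inflammation",
              "Glazing, redness, edema, and/or hypertrophy of the marginal or "
              "papillary gingival unit",
              "Red or reddish-blue", "Glazy",
              "Edema and/or hypertrophy of the margin", "Entire gingival unit"),
    RubricRow(4, "Severe inflammation",
              "Marked redness, edema, and/or hypertrophy of the marginal or "
              "papillary gingival unit, spontaneous bleeding congestion, or "
              "ulceration",
              "Markedly red or reddish-blue", "Spontaneous bleeding or ulceration",
              "Edema and/or hypertrophy of the entire unit", "Entire gingival unit"),
)

VALID_SCORES = frozenset(range(5))


@dataclass(frozen=True)
class GIScore:
    """One rater's modified-GI score for one site at one time point."""

    subject_id: str
    site: str
    timepoint: str
    score: int
    rater_id: str = "rater1"

    def __post_init__(self):
        if self.score not in VALID_SCORES:
            raise ScoreValidationError(
                f"GI score must be an integer 0-4, got {self.score!r} "
                f"({self.subject_id}/{self.site}/{self.timepoint})"
            )
        if self.site not in SITES:
            raise ScoreValidationError(f"unknown site {self.site!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ScoreValidationError(f"unknown timepoint {self.timepoint!r}")


def describe_score(score: int) -> RubricRow:
    """Return the rubric row for a 0-4 score."""
    if score not in VALID_SCORES:
        raise ScoreValidationError(f"GI score must be 0-4, got {score!r}")
    return GI_RUBRIC[score]


def validate_scores(scores: list[GIScore]) -> list[GIScore]:
    """Validate a score list; duplicates by (subject, site, timepoint, rater) rejected.

    Idempotent: re-validating the returned list yields it unchanged.
    """
    seen: set[tuple] = set()
    for rec in scores:
        if not isinstance(rec, GIScore):
            raise ScoreValidationError(f"not a GIScore record: {rec!r}")
        key = (rec.subject_id, rec.site, rec.timepoint, rec.rater_id)
        if key in seen:
            raise ScoreValidationError(f"duplicate score record for {key}")
        seen.add(key)
    return list(scores)


@dataclass(frozen=True)
class ConcordanceResult:
    """Duplicate-scoring agreement between two raters.

    ``agreement`` is the fraction of matched (subject, site, timepoint) pairs
    with identical scores; ``kappa`` is Cohen's kappa over the same pairs, a
    chance-corrected supplement.
    """

    agreement: float
    n_pairs: int
    n_unmatched_primary: int
    n_unmatched_duplicate: int
    kappa: float

    def __float__(self) -> float:
        return self.agreement


def _cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    levels = np.union1d(a, b)
    k = len(levels)
    if k == 1:
        return 1.0
    idx = {v: i for i, v in enumerate(levels)}
    conf = np.zeros((k, k))
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    n = conf.sum()
    po = np.trace(conf) / n
    pe = (conf.sum(axis=1) @ conf.sum(axis=0)) / n**2
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1 - pe))


def concordance(primary: list[GIScore], duplicate: list[GIScore]) -> ConcordanceResult:
    """Percent agreement between a primary and a duplicate scoring pass.

    Records are matched by (subject, site, timepoint); unmatched records on
    either side are excluded from the fraction and counted in the result.
    """
    pmap = {(s.subject_id, s.site, s.timepoint): s.score for s in validate_scores(primary)}
    dmap = {(s.subject_id, s.site, s.timepoint): s.score for s in validate_scores(duplicate)}
    common = sorted(set(pmap) & set(dmap))
    if not common:
        raise InsufficientDataError("no matched (subject, site, timepoint) pairs")
    a = np.array([pmap[k] for k in common])
    b = np.array([dmap[k] for k in common])
    return ConcordanceResult(
        agreement=float(np.mean(a == b)),
        n_pairs=len(common),
        n_unmatched_primary=len(pmap) - len(common),
        n_unmatched_duplicate=len(dmap) - len(common),
        kappa=_cohen_kappa(a, b),
    )


def read_gi_scores(path: str | Path) -> list[GIScore]:
    """Read a GI scores CSV: subject_id,site,timepoint,rater_id,score."""
    df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str})
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                GIScore(
                    subject_id=str(row["subject_id"]),
                    site=str(row["site"]),
                    timepoint=str(row["timepoint"]),
                    score=int(row["score"]),
                    rater_id=str(row.get("rater_id", "rater1")),
                )
            )
        except (ScoreValidationError, KeyError, ValueError) as exc:
            raise ScoreValidationError(f"row {i}: {exc}") from exc
    return validate_scores(records)


def write_gi_scores(scores: list[GIScore], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "site": s.site,
                "timepoint": s.timepoint,
                "rater_id": s.rater_id,
                "score": s.score,
            }
            for s in scores
        ],
        columns=["subject_id", "site", "timepoint", "rater_id", "score"],
    ).to_csv(path, index=False)
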