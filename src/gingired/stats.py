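"""Nonparametric statistics for the longitudinal design.

Subjects are blocks, the four orthodontic time points are the repeated
treatments. The Friedman test (tie-corrected, since ordinal GI data are
heavily tied) asks whether the time points differ; Kendall's W is its
concordance effect size; Spearman's rho links the image-derived R/G ratio to
the visual GI. The per-jaw reduction keeps, for each subject / jaw / time
point, the highest R/G and the highest GI across that jaw's three papillary
sites — each variable reduced independently, so the maxima may come from
different sites.

p-values are asymptotic by default (chi-square for Friedman, t-approximation
for Spearman); exact within-block permutation is available for small designs
and falls back to seeded Monte-Carlo when full enumeration is infeasible.
Alongside p, results carry a significance tier at the conventional alpha of
0.05, with p <= 0.10 labeled a "tendency".
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError
from .io import JAW_SITES, TIMEPOINTS

logger = logging.getLogger(__name__)

ALPHA = 0.05
TENDENCY_ALPHA = 0.10

#: Full enumeration of within-block permutations is attempted up to this many.
_MAX_EXACT = 250_000


def significance_tier(p: float) -> str:
    if p <= ALPHA:
        return "significant"
    if p <= TENDENCY_ALPHA:
        return "tendency"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: int
    p_value: float
    method: str  # "chi2_approx", "t_approx", "exact_permutation", "mc_permutation"
    effect: float  # Kendall's W for Friedman; rho for Spearman
    n: int
    tier: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value outside [0, 1]: {self.p_value}")
        if not self.tier:
            object.__setattr__(self, "tier", significance_tier(self.p_value))


def _block_ranks(data: np.ndarray) -> np.ndarray:
    """Average ranks within each row (block); ties share the mean rank."""
    return np.apply_along_axis(sps.rankdata, 1, data)


def _friedman_core(data: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square and Kendall's W for an n x k matrix."""
    n, k = data.shape
    ranks = _block_ranks(data)
    col_sums = ranks.sum(axis=0)
    ssbn = float((col_sums**2).sum())
    # tie term: sum over blocks of (t^3 - t) for each tie group of size t
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    num = (k - 1) * (12.0 * ssbn - 3.0 * n**2 * k * (k + 1) ** 2)
    denom = n * k * (k**2 - 1) - ties
    if denom <= 0:  # every block fully tied: no information
        return 0.0, 0.0
    chi2 = num / denom
    w = chi2 / (n * (k - 1))
    return chi2, float(np.clip(w, 0.0, 1.0))


def friedman_test(
    data: np.ndarray | pd.DataFrame,
    exact: bool = False,
    n_mc: int = 20_000,
    seed: int | None = None,
) -> TestResult:
    """Friedman test across k repeated treatments in n blocks.

    ``data`` is an n x k matrix (rows = subjects, columns = time points), no
    missing cells. The statistic is tie-corrected; p comes from the
    chi-square approximation with k-1 df, or from within-block permutation
    when ``exact=True`` (full enumeration of (k!)^n orderings when feasible,
    otherwise ``n_mc`` seeded Monte-Carlo draws).
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise ParameterError("Friedman input must be a 2-D blocks x treatments matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(f"need >= 2 blocks and >= 2 treatments, got {x.shape}")
    if np.isnan(x).any():
        raise ParameterError("missing cells are not allowed; drop incomplete blocks first")
    chi2, w = _friedman_core(x)
    if not exact:
        p = float(sps.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
        return TestResult(chi2, k - 1, p, "chi2_approx", w, n)

    ranks = _block_ranks(x)
    obs = float((ranks.sum(axis=0) ** 2).sum())
    n_full = math.factorial(k) ** n
    perms = np.array(list(itertools.permutations(range(k))))
    if n_full <= _MAX_EXACT:
        count, total = 0, 0
        for choice in itertools.product(range(len(perms)), repeat=n):
            cols = ranks[np.arange(n)[:, None], perms[np.array(choice)]]
            stat = float((cols.sum(axis=0) ** 2).sum())
            count += stat >= obs - 1e-12
            total += 1
        return TestResult(chi2, k - 1, count / total, "exact_permutation", w, n)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(perms), size=(n_mc, n))
    count = 0
    for d in draws:
        cols = ranks[np.arange(n)[:, None], perms[d]]
        count += float((cols.sum(axis=0) ** 2).sum()) >= obs - 1e-12
    # add-one correction keeps Monte-Carlo p valid
    return TestResult(chi2, k - 1, (count + 1) / (n_mc + 1), "mc_permutation", w, n)


def kendalls_w(data: np.ndarray | pd.DataFrame) -> float:
    """Tie-corrected Kendall's coefficient of concordance W in [0, 1].

    Satisfies W = chi2_friedman / (n (k-1)) with the tie-corrected statistic.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError("need an n x k matrix with n >= 2, k >= 2")
    if np.isnan(x).any():
        raise ParameterError("missing cells are not allowed")
    return _friedman_core(x)[1]


def spearman_rho(
    x: np.ndarray,
    y: np.ndarray,
    exact: bool = False,
) -> TestResult:
    """Spearman rank correlation with tie handling (average ranks).

    p is the t-approximation with n-2 df; with ``exact=True`` and n <= 8, a
    full permutation of one margin gives the two-sided exact p.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("rho undefined for a constant margin")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if exact:
        if n > 8:
            raise ParameterError("exact permutation p supported for n <= 8 only")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count, total = 0, 0
        for perm in itertools.permutations(ry):
            count += abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12
            total += 1
        return TestResult(rho, n - 2, count / total, "exact_permutation", rho, n)
    return TestResult(rho, n - 2, float(res.pvalue), "t_approx", rho, n)


def max_site_per_jaw(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce to the highest value per (subject, jaw, timepoint).

    The maximum R/G and the maximum GI across the jaw's three papillary sites
    are taken independently (they may come from different sites). Groups with
    no R/G value are dropped with a log entry; GI is reduced where present.
    """
    required = {"subject_id", "jaw", "timepoint", "rg_ratio"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"table missing columns: {sorted(missing)}")
    df = table.copy()
    has_gi = "gi" in df.columns
    groups = df.groupby(["subject_id", "jaw", "timepoint"], sort=True)
    rows = []
    for (subj, jaw, tp), grp in groups:
        rg = grp["rg_ratio"].dropna()
        if rg.empty:
            logger.warning("dropping (%s, %s, %s): no R/G values", subj, jaw, tp)
            continue
        row = {"subject_id": subj, "jaw": jaw, "timepoint": tp, "rg_ratio": float(rg.max())}
        if has_gi:
            gi = grp["gi"].dropna()
            row["gi"] = float(gi.max()) if not gi.empty else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def gi_rg_correlation_matrix(reduced: pd.DataFrame, exact: bool = False) -> pd.DataFrame:
    """Spearman rho between highest GI and highest R/G, per jaw and time point.

    Expects the output of :func:`max_site_per_jaw` with both variables. One
    row per (jaw, timepoint) with rho, p_value, n and tier; a cell with fewer
    than 3 subjects or a constant margin is reported with NaN rho and an
    ``error`` note instead of aborting the others.
    """
    if "gi" not in reduced.columns:
        raise ParameterError("reduced table has no 'gi' column")
    rows = []
    for jaw in ("maxilla", "mandible"):
        for tp in TIMEPOINTS:
            cell = reduced[(reduced["jaw"] == jaw) & (reduced["timepoint"] == tp)]
            cell = cell.dropna(subset=["gi", "rg_ratio"])
            rec = {"jaw": jaw, "timepoint": tp, "n": len(cell)}
            try:
                res = spearman_rho(cell["rg_ratio"].to_numpy(), cell["gi"].to_numpy(),
                                   exact=exact and len(cell) <= 8)
                rec.update(rho=res.effect, p_value=res.p_value, tier=res.tier, error="")
            except (InsufficientDataError, ParameterError) as exc:
                rec.update(rho=np.nan, p_value=np.nan, tier="", error=str(exc))
            rows.append(rec)
    return pd.DataFrame(rows)


def longitudinal_summary(
    table: pd.DataFrame,
    value: str = "rg_ratio",
    exact: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-site mean ± SD by time point plus Friedman / Kendall's W results.

    Only complete blocks enter the test: subjects observed at all four time
    points for the site; incomplete subjects are dropped with a log entry.
    One row per site with mean_<tp>, sd_<tp> columns, the tie-corrected
    Friedman chi-square, its p-value, Kendall's W, and the n used.
    """
    required = {"subject_id", "site", "timepoint", value}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"table missing columns: {sorted(missing)}")
    rows = []
    any_complete = False
    for site, grp in table.groupby("site", sort=False):
        wide = grp.pivot_table(index="subject_id", columns="timepoint",
                               values=value, aggfunc="first")
        wide = wide.reindex(columns=list(TIMEPOINTS))
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.warning("site %s: dropped %d incomplete subjects", site, n_dropped)
        row: dict = {"site": site, "n": len(complete)}
        for tp in TIMEPOINTS:
            col = complete[tp] if not complete.empty else grp.loc[grp["timepoint"] == tp, value]
            row[f"mean_{tp}"] = float(col.mean()) if len(col) else np.nan
            row[f"sd_{tp}"] = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        if len(complete) >= 2:
            any_complete = True
            res = friedman_test(complete.to_numpy(), exact=exact, seed=seed)
            row.update(friedman_chi2=res.statistic, p_value=res.p_value,
                       kendalls_w=res.effect, tier=res.tier)
        else:
            row.update(friedman_chi2=np.nan, p_value=np.nan, kendalls_w=np.nan, tier="")
        rows.append(row)
    if not any_complete:
        raise InsufficientDataError("no site has >= 2 complete blocks")
    return pd.DataFrame(rows)
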