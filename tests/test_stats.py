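import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gingired import (
    InsufficientDataError,
    ParameterError,
    friedman_test,
    gi_rg_correlation_matrix,
    kendalls_w,
    longitudinal_summary,
    max_site_per_jaw,
    spearman_rho,
)
from gingired.io import JAW_SITES, SITES, TIMEPOINTS
from gingired.stats import _block_ranks
from gingired.synthetic import generate_linked_reduced_table


class TestFriedman:
    def test_perfect_concordance_statistic(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        res = friedman_test(x)
        assert res.statistic == pytest.approx(10 * 3)  # n (k-1) with W = 1
        assert res.effect == pytest.approx(1.0)

    def test_all_equal_gives_zero_statistic_p_one(self):
        res = friedman_test(np.ones((6, 4)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=(12, 4)).astype(float)  # ordinal-like, heavy ties
        res = friedman_test(x)
        ref = sps.friedmanchisquare(*(x[:, j] for j in range(4)))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_permutation_matches_brute_force_oracle(self):
        x = np.array([[1.2, 0.7, 2.5], [0.1, 0.9, 0.4], [2.0, 1.1, 1.5]])
        res = friedman_test(x, exact=True)
        assert res.method == "exact_permutation"
        obs = sps.friedmanchisquare(*(x[:, j] for j in range(3))).statistic
        count = total = 0
        for rows in itertools.product(*(itertools.permutations(row) for row in x)):
            m = np.array(rows)
            stat = sps.friedmanchisquare(*(m[:, j] for j in range(3))).statistic
            count += stat >= obs - 1e-12
            total += 1
        assert total == 216
        assert res.p_value == pytest.approx(count / total)

    def test_monte_carlo_close_to_chi2_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 4))
        p_mc = friedman_test(x, exact=True, n_mc=20000, seed=0).p_value
        p_chi2 = friedman_test(x).p_value
        assert abs(p_mc - p_chi2) < 0.05

    def test_missing_cells_rejected(self):
        x = np.ones((4, 4))
        x[0, 0] = np.nan
        with pytest.raises(ParameterError):
            friedman_test(x)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(9, 4))
        a = friedman_test(x)
        b = friedman_test(np.exp(x))  # strictly monotone transform
        assert a.statistic == pytest.approx(b.statistic)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000), st.integers(2, 8), st.integers(2, 6))
    def test_block_rank_sums_conserved(self, seed, n, k):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=(n, k)).astype(float)
        ranks = _block_ranks(x)
        np.testing.assert_allclose(ranks.sum(axis=1), k * (k + 1) / 2)


class TestKendallsW:
    def test_perfect_agreement(self):
        assert kendalls_w(np.tile([3.0, 1.0, 2.0, 4.0], (7, 1))) == pytest.approx(1.0)

    def test_identity_with_friedman(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.integers(0, 5, size=(10, 4)).astype(float)
            res = friedman_test(x)
            assert kendalls_w(x) == pytest.approx(res.statistic / (10 * 3))

    def test_k2_identity_holds(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 2))
        res = friedman_test(x)
        assert kendalls_w(x) == pytest.approx(res.statistic / (15 * 1))

    def test_near_zero_under_independence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 4))
        assert kendalls_w(x) < 0.1


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(1.0, 11.0)
        res = spearman_rho(x, x**2)
        assert res.effect == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(1.0, 11.0)
        assert spearman_rho(x, x[::-1]).effect == pytest.approx(-1.0)

    def test_tied_data_matches_hand_assigned_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        # hand ranks: x -> 1, 2.5, 2.5, 4, 5, 6 ; y -> 2, 1, 4, 3, 6, 5
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).effect == pytest.approx(expected)

    def test_exact_permutation_matches_enumeration_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = spearman_rho(x, y, exact=True)
        obs = abs(sps.spearmanr(x, y).statistic)
        count = total = 0
        for perm in itertools.permutations(y):
            count += abs(sps.spearmanr(x, np.array(perm)).statistic) >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = spearman_rho(x, y), spearman_rho(y, x)
        assert a.effect == pytest.approx(b.effect)
        assert -1.0 <= a.effect <= 1.0
        assert spearman_rho(x, x).effect == pytest.approx(1.0)

    def test_constant_margin_rejected(self):
        with pytest.raises(ParameterError):
            spearman_rho(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman_rho(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


def _cohort_frame(n_subjects=4, rg=None, gi=None, seed=0):
    """Long-format frame covering all subjects x sites x timepoints."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for site in SITES:
            for tp in TIMEPOINTS:
                rows.append({
                    "subject_id": f"S{s:02d}", "site": site,
                    "jaw": "maxilla" if site.startswith("U_") else "mandible",
                    "timepoint": tp,
                    "rg_ratio": rg if rg is not None else rng.uniform(1.4, 1.9),
                    "gi": gi if gi is not None else int(rng.integers(0, 5)),
                })
    return pd.DataFrame(rows)


class TestMaxSitePerJaw:
    def test_takes_the_maximum_across_sites(self):
        df = _cohort_frame(n_subjects=1)
        df = df[df["timepoint"] == "BO"].copy()
        df.loc[df["jaw"] == "maxilla", "rg_ratio"] = [1.5, 1.7, 1.6]
        red = max_site_per_jaw(df)
        row = red[(red["jaw"] == "maxilla")]
        assert row["rg_ratio"].item() == pytest.approx(1.7)

    def test_maxima_taken_independently_per_variable(self):
        df = _cohort_frame(n_subjects=1)
        df = df[(df["timepoint"] == "BO") & (df["jaw"] == "maxilla")].copy()
        df["rg_ratio"] = [1.5, 1.9, 1.6]
        df["gi"] = [4, 0, 1]  # max GI at a different site than max R/G
        red = max_site_per_jaw(df)
        assert red["rg_ratio"].item() == pytest.approx(1.9)
        assert red["gi"].item() == 4

    def test_single_site_is_identity(self):
        df = _cohort_frame(n_subjects=1)
        df = df[(df["site"] == "U_11_21") & (df["timepoint"] == "MO")]
        red = max_site_per_jaw(df)
        assert red["rg_ratio"].item() == pytest.approx(df["rg_ratio"].item())

    def test_reduced_row_count(self):
        df = _cohort_frame(n_subjects=5)
        red = max_site_per_jaw(df)
        assert len(red) == 5 * 2 * len(TIMEPOINTS)


class TestCorrelationMatrix:
    def test_noiseless_monotone_link_gives_rho_one(self):
        df = _cohort_frame(n_subjects=10, seed=1)
        red = max_site_per_jaw(df)
        # strictly monotone noiseless link: GI = within-cell rank of R/G
        red["gi"] = red.groupby(["jaw", "timepoint"])["rg_ratio"].rank(method="first") - 1
        mat = gi_rg_correlation_matrix(red)
        assert (mat["rho"].round(9) == 1.0).all()

    def test_null_link_gives_small_rho(self):
        df = generate_linked_reduced_table(n_subjects=200, link_rho=0.01, seed=2)
        mat = gi_rg_correlation_matrix(df)
        assert (mat["rho"].abs() < 0.15).all()

    def test_planted_link_recovered(self):
        df = generate_linked_reduced_table(n_subjects=100, link_rho=0.8, seed=3)
        mat = gi_rg_correlation_matrix(df)
        assert len(mat) == 8  # 2 jaws x 4 time points
        assert ((mat["rho"] - 0.8).abs() <= 0.1).all()

    def test_insufficient_cell_flagged_not_fatal(self):
        df = generate_linked_reduced_table(n_subjects=2, link_rho=0.5, seed=4)
        mat = gi_rg_correlation_matrix(df)
        assert mat["rho"].isna().all()
        assert (mat["error"] != "").all()


class TestLongitudinalSummary:
    def test_constant_table(self):
        df = _cohort_frame(n_subjects=4, rg=1.6)
        summ = longitudinal_summary(df)
        assert len(summ) == len(SITES)
        for tp in TIMEPOINTS:
            assert (summ[f"sd_{tp}"] == 0).all()
        assert (summ["p_value"] == 1.0).all()

    def test_planted_time_effect_recovered(self):
        rng = np.random.default_rng(9)
        means = {"BO": 1.62, "MO": 1.52, "TO": 1.66, "IDO": 1.76}
        rows = []
        for s in range(25):
            eff = rng.normal(0, 0.05)
            for site in SITES:
                for tp in TIMEPOINTS:
                    rows.append({"subject_id": f"S{s}", "site": site, "timepoint": tp,
                                 "rg_ratio": means[tp] + eff + rng.normal(0, 0.03)})
        summ = longitudinal_summary(pd.DataFrame(rows))
        assert (summ["p_value"] < 0.05).all()
        for _, row in summ.iterrows():
            order = sorted(TIMEPOINTS, key=lambda tp: row[f"mean_{tp}"])
            assert order == ["MO", "BO", "TO", "IDO"]

    def test_incomplete_subjects_dropped(self, caplog):
        df = _cohort_frame(n_subjects=5, seed=10)
        df = df[~((df["subject_id"] == "S00") & (df["timepoint"] == "IDO"))]
        with caplog.at_level("WARNING"):
            summ = longitudinal_summary(df)
        assert (summ["n"] == 4).all()
        assert "incomplete" in caplog.text

    def test_no_complete_blocks_is_an_error(self):
        df = _cohort_frame(n_subjects=3, seed=11)
        df = df[df["timepoint"] != "IDO"]
        df = df.copy()
        # every subject misses IDO entirely -> no complete 4-timepoint block
        with pytest.raises(InsufficientDataError):
            longitudinal_summary(df)
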