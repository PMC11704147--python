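"""Statistical battery: hand/enumeration oracles and reference agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from octavasc.phantom import TIMEPOINTS, sham_scenario, simulate_track_table
from octavasc.stats_report import (
    anova_lsd,
    build_group_table,
    depth_report,
    mannwhitney_depth,
    paired_t,
)


class TestPairedT:
    def test_equal_samples_give_t0_p1(self):
        t, p = paired_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        """diffs {1,2,3,4}: t = mean/ (sd/sqrt(n)) = 2.5 / (1.2910/2)."""
        pre = np.zeros(4)
        post = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_t(pre, post)
        sd = np.std([1, 2, 3, 4], ddof=1)
        assert t == pytest.approx(2.5 / (sd / 2.0), rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(t, df=3), rel=1e-12)

    def test_agrees_with_reference_on_100_datasets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 30)
            pre = rng.normal(1.0, 0.1, n)
            post = pre * rng.normal(1.1, 0.05, n)
            t, p = paired_t(pre, post)
            ref = sps.ttest_rel(post, pre)
            assert abs(t - ref.statistic) < 1e-9
            assert abs(p - ref.pvalue) < 1e-6

    def test_zero_variance_differences_undefined(self):
        t, p = paired_t(np.array([1.0, 2.0]), np.array([2.0, 3.0]))
        assert np.isnan(t) and np.isnan(p)


def _balanced_two_way_oracle(df):
    """Closed-form balanced two-way ANOVA sums of squares."""
    y = df["value"].to_numpy()
    grand = y.mean()
    ss_a = sum(
        len(g) * (g["value"].mean() - grand) ** 2 for _, g in df.groupby("condition")
    )
    ss_b = sum(
        len(g) * (g["value"].mean() - grand) ** 2 for _, g in df.groupby("timepoint")
    )
    ss_cells = sum(
        len(g) * (g["value"].mean() - grand) ** 2
        for _, g in df.groupby(["condition", "timepoint"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g["value"] - g["value"].mean()) ** 2).sum()
        for _, g in df.groupby(["condition", "timepoint"])
    )
    return ss_a, ss_b, ss_ab, ss_err


class TestAnovaLSD:
    def _frame(self, rng, n=6, shift=0.0):
        rows = []
        for cond in ("low", "high"):
            for tp in ("t1", "t2", "t3"):
                vals = rng.normal(1.0 + (shift if cond == "high" else 0.0), 0.05, n)
                rows += [{"condition": cond, "timepoint": tp, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_matches_closed_form_sums_of_squares(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            df = self._frame(rng, shift=rng.normal(0, 0.1))
            res = anova_lsd(df)
            tab = res["anova_table"]
            ss_a, ss_b, ss_ab, ss_err = _balanced_two_way_oracle(df)
            assert tab.loc["C(_a)", "sum_sq"] == pytest.approx(ss_a, rel=1e-6)
            assert tab.loc["C(_b)", "sum_sq"] == pytest.approx(ss_b, rel=1e-6)
            assert tab.loc["C(_a):C(_b)", "sum_sq"] == pytest.approx(ss_ab, rel=1e-6, abs=1e-12)
            assert tab.loc["Residual", "sum_sq"] == pytest.approx(ss_err, rel=1e-6)

    def test_separated_conditions_highly_significant(self):
        rng = np.random.default_rng(1)
        df = self._frame(rng, shift=0.5)
        res = anova_lsd(df)
        assert res["anova_table"].loc["C(_a)", "PR(>F)"] < 1e-3
        assert (res["lsd_pairwise"]["p"] < 1e-3).all()

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(2)
        df = self._frame(rng, shift=0.0)
        res = anova_lsd(df)
        # no pairwise comparison should reject at 0.001 under the null
        assert not (res["lsd_pairwise"]["p"] < 1e-3).any()

    def test_lsd_uses_pooled_error_term(self):
        rng = np.random.default_rng(3)
        df = self._frame(rng, shift=0.2)
        res = anova_lsd(df)
        row = res["lsd_pairwise"].iloc[0]
        sub = df[df["timepoint"] == row["timepoint"]]
        g1 = sub[sub["condition"] == row["level_1"]]["value"]
        g2 = sub[sub["condition"] == row["level_2"]]["value"]
        se = np.sqrt(res["mse"] * (1 / len(g1) + 1 / len(g2)))
        assert row["t"] == pytest.approx((g1.mean() - g2.mean()) / se, rel=1e-9)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame(
            {"condition": ["a"] * 4, "timepoint": ["t1", "t1", "t2", "t2"], "value": [1, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="at least 2 levels"):
            anova_lsd(df)


def _enumerate_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of all rank splits."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = sps.rankdata(pooled)
    obs_u = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic
    us = []
    for idx in itertools.combinations(range(n + m), n):
        r = ranks[list(idx)].sum()
        u = r - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    u_star = max(obs_u, n * m - obs_u)
    p = (np.maximum(us, n * m - us) >= u_star - 1e-9).mean()
    return p


class TestMannWhitney:
    def test_enumerated_separated_triplets(self):
        """{1,2,3} vs {10,11,12}: U = 0, exact two-sided p = 2/20 = 0.1."""
        u, p = mannwhitney_depth(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_not_significant(self):
        u, p = mannwhitney_depth(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert p > 0.9

    def test_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = rng.normal(0, 1, 4)
            y = rng.normal(rng.normal(0, 1), 1, 5)
            _, p = mannwhitney_depth(x, y)
            assert p == pytest.approx(_enumerate_mw_p(x, y), abs=1e-9)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(8)
        x = np.round(rng.normal(0, 1, 40), 1)
        y = np.round(rng.normal(0.3, 1, 35), 1)
        u, p = mannwhitney_depth(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_is_na(self):
        u, p = mannwhitney_depth(np.array([]), np.array([1.0]))
        assert u is None and p is None


class TestReports:
    def test_sham_table_near_unity(self):
        df = simulate_track_table(sham_scenario(6), seed=0)
        table = build_group_table({"sham": df})
        row = table[(table["class"] == "<15") & (table["condition"] == "sham")].iloc[0]
        for tp in ("post1_1min", "post1_10min", "post2_10min"):
            assert row[f"norm_{tp}_mean"] == pytest.approx(1.0, abs=0.03)

    def test_table_rebuild_from_csv_is_identical(self, tmp_path):
        df = simulate_track_table(sham_scenario(4), seed=3)
        t1 = build_group_table({"sham": df})
        path = tmp_path / "tracks.csv"
        df.to_csv(path, index=False)
        t2 = build_group_table({"sham": pd.read_csv(path)})
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_class_row_omitted(self):
        df = simulate_track_table(
            sham_scenario(3), n_branches_per_class={"<15": 5}, seed=1
        )
        table = build_group_table({"sham": df})
        assert set(table["class"]) == {"all", "<15"}

    def test_depth_report_counts_and_na(self):
        pre = pd.DataFrame(
            {"depth_um": [10, 20, 30, 60, 70, 80], "mean_diameter_um": [6, 7, 8, 6, 7, 8]}
        )
        post = pd.DataFrame({"depth_um": [15, 25, 35], "mean_diameter_um": [9, 9, 9]})
        res = depth_report(pre, post, bin_um=50.0, max_depth_um=100.0)
        assert res[0].n_pre == 3 and res[0].n_post == 3
        assert res[0].mannwhitney_p is not None
        assert res[1].n_pre == 3 and res[1].n_post == 0
        assert res[1].mannwhitney_p is None

    def test_no_post_data_all_na(self):
        pre = pd.DataFrame({"depth_um": [10, 20, 30], "mean_diameter_um": [6, 7, 8]})
        post = pre.iloc[:0]
        res = depth_report(pre, post, bin_um=50.0, max_depth_um=100.0)
        assert all(r.mannwhitney_p is None for r in res)
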