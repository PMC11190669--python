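"""Regression, ANOVA (raw and summary forms), Spearman, clustered comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lnscore.errors import DomainError, InsufficientDataError, ValidationError
from lnscore.stats import (
    anova_from_summary,
    clustered_compare,
    merge_summary_groups,
    ols_fit,
    oneway_anova,
    spearman_matrix,
)


class TestOls:
    def test_perfect_line(self):
        fit = ols_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(DomainError):
            ols_fit([1, 1, 1], [0, 1, 2])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            ols_fit([0, 1], [0, 1])

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = 2.0 + 0.7 * x + rng.normal(size=12)
        fit = ols_fit(x, y)
        # independent closed-form computation
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        ss_res = (resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        f = (ss_tot - ss_res) / (ss_res / (len(x) - 2))
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert fit.f_stat == pytest.approx(f, rel=1e-9)
        assert fit.p_value == pytest.approx(float(sps.f.sf(f, 1, len(x) - 2)), rel=1e-9)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)

    def test_prediction_band_contains_confidence_band(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        fit = ols_fit(x, y)
        assert (fit.prediction_band[:, 0] < fit.confidence_band[:, 0]).all()
        assert (fit.prediction_band[:, 1] > fit.confidence_band[:, 1]).all()


class TestAnova:
    def test_equal_means_zero_f(self):
        res = oneway_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values(self):
        res = oneway_anova([[5.0, 5.0], [5.0, 5.0]])
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=11)
        res = oneway_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_brute_force_ss_oracle(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1.0, size=n) for m, n in [(0, 5), (0.5, 7), (1.0, 4)]]
        res = oneway_anova(groups)
        # oracle: direct double loop over observations
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum((v - g.mean()) ** 2 for g in groups for v in g)
        sst = sum((v - grand) ** 2 for v in allv)
        assert res.ss_between == pytest.approx(ssb, abs=1e-10)
        assert res.ss_within == pytest.approx(ssw, abs=1e-10)
        assert ssb + ssw == pytest.approx(sst, abs=1e-10)
        f = (ssb / 2) / (ssw / (len(allv) - 3))
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.f_stat == pytest.approx(
            sps.f_oneway(*groups).statistic, rel=1e-10
        )  # independent library route

    @given(
        data=st.lists(
            st.lists(st.floats(-50, 50), min_size=2, max_size=6),
            min_size=2, max_size=4,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_sum_of_squares_conservation(self, data):
        res = oneway_anova(data)
        allv = np.concatenate([np.asarray(g) for g in data])
        sst = ((allv - allv.mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(sst, abs=1e-6 * (1 + sst))

    def test_summary_form_matches_raw_form(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1.0, size=n) for m, n in [(0, 6), (1, 9), (2, 5)]]
        raw = oneway_anova(groups)
        summ = anova_from_summary(
            [(len(g), float(g.mean()), float(g.std(ddof=1))) for g in groups]
        )
        assert summ.f_stat == pytest.approx(raw.f_stat, rel=1e-9)
        assert summ.p_value == pytest.approx(raw.p_value, rel=1e-9)
        assert summ.r_squared == pytest.approx(raw.r_squared, rel=1e-9)

    def test_singleton_group_with_sd_rejected(self):
        with pytest.raises(ValidationError):
            anova_from_summary([(1, 0.0, 2.0), (5, 1.0, 1.0)])

    def test_merge_preserves_total_sum_of_squares(self):
        stats4 = [(9, -44.65, 43.34), (18, -24.19, 24.94), (19, -15.69, 25.48), (9, -3.66, 22.12)]
        full = anova_from_summary(stats4)
        merged = merge_summary_groups(stats4, [[0, 1], [2, 3]])
        two = anova_from_summary(merged)
        assert full.ss_between + full.ss_within == pytest.approx(
            two.ss_between + two.ss_within, rel=1e-12
        )
        # pooled means are the weighted means
        assert merged[0][1] == pytest.approx((9 * -44.65 + 18 * -24.19) / 27, rel=1e-12)


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [10, 20, 25, 40], "c": [4, 3, 2, 1]})
        m = spearman_matrix(df)
        assert m.rho.loc["a", "b"] == pytest.approx(1.0)
        assert m.rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m.rho), 1.0)
        assert np.allclose(m.rho.values, m.rho.values.T, equal_nan=True)

    def test_tied_example_against_rank_oracle(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0]
        b = [2.0, 2.0, 4.0, 4.0, 5.0]
        m = spearman_matrix(pd.DataFrame({"a": a, "b": b}))
        ra = sps.rankdata(a)  # average ranks for ties
        rb = sps.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert m.rho.loc["a", "b"] == pytest.approx(oracle, rel=1e-12)

    def test_pairwise_complete_and_min_pairs(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, np.nan],
                "b": [2.0, 1.0, 4.0, np.nan, 5.0],
                "c": [1.0, np.nan, np.nan, np.nan, 2.0],
            }
        )
        m = spearman_matrix(df)
        assert m.n.loc["a", "b"] == 3
        assert m.n.loc["a", "c"] == 1
        assert np.isnan(m.rho.loc["a", "c"])  # flagged, not fabricated

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman_matrix(pd.DataFrame({"x": x, "y": y})).rho.loc["x", "y"]
        trans = spearman_matrix(
            pd.DataFrame({"x": np.exp(x), "y": y**3})
        ).rho.loc["x", "y"]
        assert trans == pytest.approx(base, rel=1e-12)


class TestClusteredCompare:
    def test_all_values_equal(self):
        res = clustered_compare(
            [1.0] * 8, ["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4"],
            ["a"] * 4 + ["b"] * 4,
        )
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0

    def test_degenerate_clustering_matches_welch(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=9)
        b = rng.normal(0.8, 1.3, size=12)
        y = np.concatenate([a, b])
        res = clustered_compare(
            y, [f"c{i}" for i in range(21)], ["a"] * 9 + ["b"] * 12
        )
        se_welch = np.sqrt(a.var(ddof=1) / 9 + b.var(ddof=1) / 12)
        assert res.mean_difference == pytest.approx(b.mean() - a.mean(), rel=1e-12)
        assert res.robust_se == pytest.approx(se_welch, rel=1e-9)

    def test_single_cluster_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            clustered_compare([1.0, 2.0, 3.0, 4.0], ["c1", "c1", "c2", "c3"],
                              ["a", "a", "b", "b"])

    def test_type_one_error_calibrated_under_clustering(self):
        # exchangeable clusters, ICC = 0.5, no true difference: the
        # cluster-robust test holds its level while the naive episode-level
        # t-test is badly anti-conservative
        rng = np.random.default_rng(22)
        reps = 1000
        robust_rej = naive_rej = 0
        group_ids = ["a"] * 60 + ["b"] * 60
        cluster_ids = [f"{g}{i // 4}" for i, g in enumerate(group_ids)]
        for _ in range(reps):
            cluster_effects = rng.normal(0, 1.0, 30)  # 15 clusters per group
            y = cluster_effects[
                np.arange(120) // 4
            ] + rng.normal(0, 1.0, 120)
            res = clustered_compare(y, cluster_ids, group_ids)
            robust_rej += res.p_value < 0.05
            naive_rej += sps.ttest_ind(y[:60], y[60:]).pvalue < 0.05
        lo, hi = sps.binom.ppf([0.001, 0.999], reps, 0.05)
        assert lo <= robust_rej <= hi, robust_rej
        assert naive_rej / reps > 0.15, naive_rej

    def test_cluster_spanning_groups_rejected(self):
        with pytest.raises(ValidationError):
            clustered_compare(
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                ["c1", "c2", "c1", "c3", "c4", "c5"],
                ["a", "a", "b", "b", "a", "b"],
            )
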