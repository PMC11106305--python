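"""Effect sizes, t-tests, Sidak adjustment, ANOVA and ratio summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mixedbeam.additivity import round_half_away
from mixedbeam.stats import (
    classify_effect,
    cohens_d_one_sample,
    cohens_d_two_sample,
    one_way_anova,
    ratio_heat_table,
    seasonal_summary,
    sidak_adjust,
    significance_stars,
    t_test_one_sample,
    t_test_two_sample,
)


class TestCohensD:
    @pytest.mark.parametrize(
        "m1, s1, n1, m2, s2, n2, printed",
        [
            (2.86, 0.73, 9, 2.75, 1.15, 9, 0.11),  # donor 1 alphas vs MB RBE
            (3.23, 0.62, 9, 2.61, 0.82, 9, 0.85),  # donor 2
            (3.00, 0.87, 18, 2.73, 0.78, 18, 0.33),  # pooled
        ],
    )
    def test_printed_rbe_effect_sizes(self, m1, s1, n1, m2, s2, n2, printed):
        d = cohens_d_two_sample(m1, s1, n1, m2, s2, n2).d
        assert round_half_away(d, 2) == printed

    def test_equal_group_sizes_reduce_to_rms_sd(self):
        d = cohens_d_two_sample(3.0, 0.5, 10, 2.0, 0.7, 10).d
        assert d == pytest.approx(1.0 / math.sqrt((0.25 + 0.49) / 2))

    def test_equal_means_give_zero(self):
        assert cohens_d_two_sample(2.0, 0.5, 5, 2.0, 0.7, 5).d == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        m=st.floats(-10, 10, allow_nan=False),
        s=st.floats(0.1, 5, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
        shift=st.floats(-20, 20, allow_nan=False),
    )
    def test_affine_invariance(self, m, s, scale, shift):
        d0 = cohens_d_two_sample(m, s, 8, m + 1, s, 8).d
        d1 = cohens_d_two_sample(scale * m + shift, scale * s, 8, scale * (m + 1) + shift, scale * s, 8).d
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_one_sample_examples(self):
        vals = [1.0, 1.5, 2.0]  # mean 1.5, sd 0.5
        assert cohens_d_one_sample(vals, 1.0).d == pytest.approx(1.0)
        assert cohens_d_one_sample([0.9, 1.0, 1.1], 1.0).d == pytest.approx(0.0)

    def test_one_sample_zero_sd_errors(self):
        with pytest.raises(ValueError):
            cohens_d_one_sample([1.0, 1.0], 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cohens_d_two_sample(1, 0.5, 1, 2, 0.5, 9)
        with pytest.raises(ValueError):
            cohens_d_two_sample(1, 0.0, 9, 2, 0.0, 9)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "d, cls",
        [
            (0.0, "small"),
            (0.5, "small"),
            (0.6, "medium"),
            (0.8, "medium"),
            (0.9, "large"),
            (1.29, "large"),
            (1.3, "very_large"),
            (-1.5, "very_large"),
        ],
    )
    def test_boundaries_on_abs_d(self, d, cls):
        assert classify_effect(d) == cls


class TestTTests:
    def test_identical_groups_t_zero_p_one(self):
        res = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_agree_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        g1 = 0.0 + rng.normal(0, 1e-3, 4)
        g2 = 1.0 + rng.normal(0, 1e-3, 4)
        res = t_test_two_sample(g1, g2)
        assert res.p_value < 1e-4
        perm = sps.permutation_test(
            (g1, g2), lambda a, b: np.mean(a) - np.mean(b),
            permutation_type="independent", n_resamples=10000, random_state=1,
        )
        assert perm.pvalue < 0.05  # exhausts the 70 splits: min p = 2/70

    def test_p_matches_t_cdf_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g1, g2 = rng.normal(0, 1, 6), rng.normal(0.5, 1.3, 9)
            res = t_test_two_sample(g1, g2)
            # independently coded pooled t and survival-function evaluation
            n1, n2 = len(g1), len(g2)
            sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
            t = (g1.mean() - g2.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
            assert res.statistic == pytest.approx(t, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_one_sample_example(self):
        res = t_test_one_sample([1.4, 1.5, 1.6], 1.0)
        assert res.statistic == pytest.approx(0.5 / (0.1 / math.sqrt(3)), rel=1e-6)
        assert res.p_value == pytest.approx(2 * sps.t.sf(res.statistic, 2), rel=1e-9)

    def test_one_sample_shift_invariance(self):
        a = t_test_one_sample([1.4, 1.5, 1.6], 1.0)
        b = t_test_one_sample([11.4, 11.5, 11.6], 11.0)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_one_sample_zero_sd_degenerates_to_equality_check(self):
        assert t_test_one_sample([1.0, 1.0, 1.0], 1.0).p_value == 1.0
        assert t_test_one_sample([2.0, 2.0, 2.0], 1.0).p_value == 0.0

    def test_paired_variant(self):
        g1, g2 = [1.0, 2.0, 3.0, 4.0], [1.1, 2.2, 3.1, 4.3]
        res = t_test_two_sample(g1, g2, paired=True)
        stat, p = sps.ttest_rel(g1, g2)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


class TestSidak:
    def test_worked_example(self):
        assert sidak_adjust(0.01, 3) == pytest.approx(0.029701)

    def test_single_comparison_identity_and_zero(self):
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)
        assert sidak_adjust(0.0, 10) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(p=st.floats(1e-9, 1), q=st.floats(1e-9, 1), m=st.integers(1, 50))
    def test_monotone_in_p_and_at_least_raw(self, p, q, m):
        tol = 1e-7  # orderings hold up to floating-point rounding of (1-p)^m
        lo, hi = sorted([p, q])
        assert sidak_adjust(lo, m) <= sidak_adjust(hi, m) * (1 + tol)
        assert sidak_adjust(p, m) >= p * (1 - tol)
        assert sidak_adjust(p, m) <= sidak_adjust(p, m + 1) * (1 + tol)
        assert 0.0 <= sidak_adjust(p, m) <= 1.0


def anova_ss_oracle(groups):
    """Independent sum-of-squares decomposition for the omnibus F."""
    allv = np.concatenate(groups)
    ss_total = np.sum((allv - allv.mean()) ** 2)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    ss_between = ss_total - ss_within
    k, n = len(groups), allv.size
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestOneWayAnova:
    def test_constant_groups_f_zero_p_one(self):
        res = one_way_anova([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_f_is_t_squared(self):
        g1, g2 = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0, 8.0]
        res = one_way_anova([g1, g2])
        t = t_test_two_sample(g1, g2)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_matches_ss_decomposition_and_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 8)) for _ in range(3)]
            res = one_way_anova(groups)
            assert res.f_statistic == pytest.approx(anova_ss_oracle(groups), rel=1e-9)
            f, p = sps.f_oneway(*groups)
            assert res.f_statistic == pytest.approx(f, rel=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_pairwise_use_within_ms_and_sidak(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [5.0, 6.0, 9.0]}
        res = one_way_anova(groups)
        assert len(res.comparisons) == 3
        for c in res.comparisons:
            assert c.degrees_of_freedom == res.df_within
            assert c.p_adjusted == pytest.approx(sidak_adjust(c.p_value, 3))
            assert c.p_adjusted >= c.p_value
            assert c.stars == significance_stars(c.p_adjusted)

    def test_degenerate_groups_error(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], [3.0]])


class TestStars:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.5, "ns"), (0.04, "ns"), (0.03, "*"), (0.002, "**"),
         (0.00015, "***"), (0.00005, "****")],
    )
    def test_threshold_convention(self, p, stars):
        assert significance_stars(p) == stars


def _ratio_frame(ratios, donor="d1", season=1, endpoint="ABER"):
    n = len(ratios)
    return pd.DataFrame(
        {
            "donor": [donor] * n,
            "season": [season] * n,
            "week": list(range(1, n + 1)),
            "endpoint": [endpoint] * n,
            "ratio": ratios,
            "defined": [not math.isnan(r) for r in ratios],
        }
    )


class TestSeasonalSummary:
    def test_all_ones_mean_one_effect_undefined(self):
        s = seasonal_summary(_ratio_frame([1.0, 1.0, 1.0]), "d1", 1)
        assert s.ratio_mean == 1.0
        assert s.test_vs_one.p_value == 1.0  # zero-sd equality check

    def test_shifted_ratios_detected(self):
        rng = np.random.default_rng(5)
        ratios = list(1.4 + rng.normal(0, 0.05, 21))
        s = seasonal_summary(_ratio_frame(ratios), "d1", 1)
        assert s.ratio_mean == pytest.approx(1.4, abs=0.05)
        assert s.test_vs_one.p_value < 1e-6
        assert s.test_vs_one.effect.magnitude_class == "very_large"

    def test_undefined_ratios_excluded_and_counted(self):
        s = seasonal_summary(_ratio_frame([1.2, 1.4, float("nan")]), "d1", 1)
        assert s.n_ratios == 2 and s.n_undefined == 1
        assert s.ratio_mean == pytest.approx(1.3)

    def test_too_few_defined_errors(self):
        with pytest.raises(ValueError):
            seasonal_summary(_ratio_frame([1.0, float("nan")]), "d1", 1)


class TestRatioHeatTable:
    def test_values_fall_in_containing_bins(self):
        frame = _ratio_frame([1.0, -0.5, 2.5])
        table = ratio_heat_table(frame)
        assert table.loc[0, "bin"] == "(0.9, 1.1]"
        assert table.loc[1, "bin"] == "(-inf, 0.75]"
        assert table.loc[2, "bin"] == "(1.75, inf]"

    def test_undefined_ratio_labelled(self):
        table = ratio_heat_table(_ratio_frame([1.0, float("nan")]))
        assert table.loc[1, "bin"] == "undefined"

    def test_row_count_is_endpoints_times_weeks(self, demo_study):
        from mixedbeam import pipeline

        fits = pd.concat(
            [pipeline.aberration_fits(demo_study.metaphases),
             pipeline.expression_fits(demo_study.ct)],
            ignore_index=True,
        )
        synergy = pipeline.weekly_synergy(fits)
        table = ratio_heat_table(synergy)
        assert len(table) == 2 * 7 * 9  # donors x endpoints x (seasons x weeks)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            ratio_heat_table(_ratio_frame([1.0]), bin_edges=(0, 1, 1))
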