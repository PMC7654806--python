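import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apcsim import (
    ArrivalModel,
    GroupSummary,
    accuracy_pct,
    disagreement_rate,
    lps_accuracy_correlation,
    run_chain,
    summarize_runs,
    two_sample_ttest,
    z_error_probability,
    zscore_anova,
)
from apcsim.dispenser import DispenseRun
from apcsim.runstats import display_pct

# published per-threshold dispensing summaries (n, mean, 95% CI half-width)
THRESHOLD_GROUPS = [
    ("2.5", 10, 99.7, 1.60), ("3", 21, 97.2, 1.22), ("3.5", 20, 97.5, 1.74),
    ("4", 20, 96.2, 2.21), ("4.5", 21, 97.5, 1.66), ("5", 13, 95.9, 8.77),
    ("6", 8, 102.9, 4.16), ("7", 6, 135.5, 33.84), ("8", 5, 132.6, 34.00),
]


class TestAccuracyPct:
    @pytest.mark.parametrize("mean,target,raw,shown", [
        (262, 250, 4.8, 5),    # manual counting in the survival trials
        (233, 250, -6.8, -7),  # machine dispensing in the same trials
        (100, 100, 0.0, 0),
    ])
    def test_worked_examples(self, mean, target, raw, shown):
        val = accuracy_pct(mean, target)
        assert val == pytest.approx(raw)
        assert display_pct(val) == shown

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-50, 50), st.integers(50, 500))
    def test_antisymmetric_around_target(self, d, t):
        assert accuracy_pct(t + d, t) == pytest.approx(-accuracy_pct(t - d, t),
                                                       abs=1e-9)


class TestSummarizeRuns:
    def test_symmetric_counts(self):
        s = summarize_runs([98, 99, 100, 101, 102], 100)
        assert s.prop_98_102 == 1.0
        assert s.mean_pct_error == pytest.approx(0.0)
        assert s.prop_95_105 == 1.0

    def test_identical_runs_degenerate(self):
        s = summarize_runs([100] * 10, 100)
        assert s.ci95_halfwidth == 0.0
        assert s.mode == (100,)
        assert s.shapiro_p is None  # zero-variance sample

    def test_single_run_has_no_ci(self):
        s = summarize_runs([97], 100)
        assert s.ci95_halfwidth is None
        assert s.shapiro_p is None

    def test_tied_modes_all_reported(self):
        s = summarize_runs([98, 98, 99, 99, 100], 100)
        assert s.mode == (98, 99)

    def test_shapiro_matches_reference(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(100, 3, 500)).astype(int)
        s = summarize_runs(list(x), 100)
        ref = stats.shapiro(x.astype(float)).pvalue
        assert s.shapiro_p == pytest.approx(ref, abs=1e-6)

    def test_skew_direction(self):
        left = [100] * 20 + [80, 70, 60]
        assert summarize_runs(left, 100).skew_direction == "left"

    def test_ci_matches_t_interval(self):
        x = [95, 99, 101, 103, 100, 98]
        s = summarize_runs(x, 100)
        err = 100.0 * (np.asarray(x, float) - 100) / 100
        lo, hi = stats.t.interval(0.95, len(x) - 1, loc=np.mean(err),
                                  scale=stats.sem(err))
        assert s.ci95_halfwidth == pytest.approx((hi - lo) / 2)


class TestAnova:
    def test_published_summary_recomputation(self):
        groups = [GroupSummary(l, n, m, ci) for l, n, m, ci in THRESHOLD_GROUPS]
        res = zscore_anova(groups)
        assert res.df_between == 8
        assert res.df_within == 115
        # limited by rounding of the published group means
        assert res.ss_between == pytest.approx(13791.628, rel=1e-3)

    def test_letter_groups_split_high_thresholds(self):
        groups = [GroupSummary(l, n, m, ci) for l, n, m, ci in THRESHOLD_GROUPS]
        letters = zscore_anova(groups).letters
        low = {letters[l] for l in ("2.5", "3", "3.5", "4", "4.5", "5", "6")}
        high = {letters[l] for l in ("7", "8")}
        assert len(low) == 1 and len(high) == 1
        assert low.isdisjoint(high)

    def test_equal_means_give_zero_f(self):
        res = zscore_anova([[5.0, 5.0, 5.0], [5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.ss_between == pytest.approx(0.0, abs=1e-20)
        assert res.f == 0.0

    def test_summary_equals_raw_anova(self):
        rng = np.random.default_rng(3)
        raw = [list(rng.normal(100 + 5 * g, 8, rng.integers(5, 15)))
               for g in range(4)]
        res_raw = zscore_anova(raw)
        summaries = []
        for i, vals in enumerate(raw):
            v = np.asarray(vals)
            half = (stats.t.ppf(0.975, len(v) - 1)
                    * np.std(v, ddof=1) / math.sqrt(len(v)))
            summaries.append(GroupSummary(str(i), len(v), float(np.mean(v)),
                                          float(half)))
        res_sum = zscore_anova(summaries)
        assert res_sum.ss_between == pytest.approx(res_raw.ss_between)
        assert res_sum.ss_within == pytest.approx(res_raw.ss_within)
        assert res_sum.f == pytest.approx(res_raw.f)
        # cross-check F against the independent reference implementation
        ref = stats.f_oneway(*raw)
        assert res_raw.f == pytest.approx(ref.statistic)
        assert res_raw.p == pytest.approx(ref.pvalue)

    def test_raw_tukey_agrees_with_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(8)
        raw = [list(rng.normal(m, 5, 12)) for m in (100, 102, 130)]
        res = zscore_anova(raw, labels=["a1", "a2", "b1"], bonferroni=False)
        values = np.concatenate(raw)
        labels = np.repeat(["a1", "a2", "b1"], 12)
        ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
        ref_reject = dict(zip([tuple(p) for p in ref._results_table.data[1:]],
                              ref.reject))
        # statsmodels rejects exactly the pairs our letters separate
        lt = res.letters
        for (g1, g2, *_), rej in ref_reject.items():
            shares = bool(set(lt[g1]) & set(lt[g2]))
            assert shares != rej

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            zscore_anova([GroupSummary("x", 5, 100.0, 1.0)])

    def test_n1_group_excluded_with_warning(self):
        groups = [GroupSummary("a", 10, 100.0, 2.0),
                  GroupSummary("b", 1, 130.0, None)]
        with pytest.warns(UserWarning):
            res = zscore_anova(groups)
        assert res.ss_within is not None


class TestCorrelation:
    @staticmethod
    def _mkrun(lps, dispensed, target=100):
        return DispenseRun(target=target, counted=target, dispensed=dispensed,
                           residual_out=0, duration=target / lps,
                           mean_lps=lps)

    def test_collinear_points(self):
        runs = [self._mkrun(10 + i, 100 + i) for i in range(5)]
        r, p = lps_accuracy_correlation(runs)
        assert r == pytest.approx(1.0)

    def test_anticollinear_points(self):
        runs = [self._mkrun(10 + i, 100 - i) for i in range(5)]
        r, _ = lps_accuracy_correlation(runs)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        runs = [self._mkrun(10, 100) for _ in range(5)]
        assert lps_accuracy_correlation(runs) == (None, None)

    def test_no_rate_effect_gives_null_p(self):
        # chains at a fixed nominal rate (no rate effect on accuracy): the
        # realized mean LPS still varies run to run, and the correlation
        # test should reject only near its nominal level
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 25
        for rep in range(n_rep):
            seed = int(rng.integers(2 ** 31))
            runs = run_chain(40, 100, ArrivalModel(lps=25), seed=seed)
            _, p = lps_accuracy_correlation(runs)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.2


class TestTTest:
    def test_identical_groups(self):
        t, df, p = two_sample_ttest(5.0, 0.0, 5, 5.0, 0.0, 5)
        assert (t, p) == (0.0, 1.0)

    def test_flow_rate_comparison_is_decisive(self):
        # high vs low reservoir flow summaries: hugely significant
        t, df, p = two_sample_ttest(0.77, 0.012, 6, 0.48, 0.007, 7)
        assert df == 11
        assert t > 0
        assert p < 1e-12

    def test_matches_reference_implementation(self):
        t, df, p = two_sample_ttest(10.0, 2.0, 12, 8.5, 2.5, 15)
        ref = stats.ttest_ind_from_stats(10.0, 2.0, 12, 8.5, 2.5, 15)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_welch_df_smaller_for_unequal_variances(self):
        _, df_w, _ = two_sample_ttest(10, 1.0, 10, 12, 5.0, 10, welch=True)
        assert df_w < 18


class TestZErrorProbability:
    def test_manufacturer_threshold(self):
        # the recommended trigger threshold of 3.5 sds
        assert z_error_probability(3.5) == pytest.approx(0.00047, abs=5e-6)

    def test_z_zero(self):
        assert z_error_probability(0.0) == 1.0

    def test_standard_quantile(self):
        assert z_error_probability(1.959964) == pytest.approx(0.05, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.0, 8.0), st.floats(0.001, 2.0))
    def test_strictly_decreasing(self, z, dz):
        assert z_error_probability(z + dz) < z_error_probability(z)


class TestDisagreementRate:
    @pytest.mark.parametrize("d,n,expected", [
        (275, 477, 57.65),  # photograph-count reconciliation rate
        (0, 10, 0.0),
        (1, 3, 33.33),
    ])
    def test_rates(self, d, n, expected):
        assert disagreement_rate(d, n) == pytest.approx(expected, abs=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            disagreement_rate(5, 3)
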