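"""SEL estimation, SEP-vs-SEL rule, paired bias comparison, and the
Fearn K/L interval for correlated standard deviations."""

import numpy as np
import pytest
from scipy import stats

from olivenir import (
    DataValidationError,
    compare_biases,
    comparison_report,
    fearn_sd_interval,
    pairwise_sd_comparisons,
    sel,
    sep_vs_sel,
)


class TestSEL:
    def test_identical_duplicates_give_zero(self):
        pairs = np.tile(np.arange(5.0)[:, None], (1, 2))
        assert sel(pairs).value == 0.0

    def test_single_differing_pair(self):
        m, d = 8, 0.6
        pairs = np.ones((m, 2))
        pairs[0, 1] += d
        assert sel(pairs).value == pytest.approx(d / np.sqrt(2 * m), abs=1e-12)
        assert sel(pairs, denominator="m").value == pytest.approx(
            d / np.sqrt(m), abs=1e-12
        )

    def test_estimates_replicate_noise_sd(self):
        """Monte-Carlo oracle: with duplicate noise sd sigma, the default
        (2m) form converges to sigma."""
        rng = np.random.default_rng(40)
        sigma = 0.37
        true = rng.uniform(10, 20, size=20000)
        pairs = true[:, None] + sigma * rng.standard_normal((20000, 2))
        assert sel(pairs).value == pytest.approx(sigma, rel=0.02)

    def test_incomplete_pairs_rejected(self):
        pairs = np.ones((3, 2))
        pairs[1, 1] = np.nan
        with pytest.raises(DataValidationError, match="1"):
            sel(pairs)


class TestSepVsSel:
    def test_table_like_case_is_good(self):
        verdict = sep_vs_sel(3.99, 2.00)
        assert verdict.good and verdict.ratio == pytest.approx(1.995)

    def test_boundary_is_strict(self):
        assert not sep_vs_sel(4.0, 2.0).good

    def test_zero_sep_always_good(self):
        assert sep_vs_sel(0.0, 0.5).good

    def test_zero_sel_with_positive_sep(self):
        verdict = sep_vs_sel(1.0, 0.0)
        assert not verdict.good and np.isinf(verdict.ratio)


class TestCompareBiases:
    def test_identical_models_ci_contains_zero(self):
        e = np.random.default_rng(41).standard_normal(30)
        res = compare_biases(e, e)
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.significant

    def test_constant_shift_is_significant(self):
        e = np.random.default_rng(42).standard_normal(30)
        res = compare_biases(e, e + 0.7)
        assert res.significant and res.mean_diff == pytest.approx(-0.7)

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(43)
        a, b = rng.standard_normal(25), rng.standard_normal(25)
        res = compare_biases(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        lo, hi = ref.confidence_interval()
        assert res.ci_low == pytest.approx(lo, abs=1e-12)
        assert res.ci_high == pytest.approx(hi, abs=1e-12)


class TestFearnInterval:
    def test_identical_errors_degenerate_to_unity(self):
        e = np.random.default_rng(44).standard_normal(20)
        res = fearn_sd_interval(e, e)
        assert res.r == 1.0
        assert res.K == pytest.approx(1.0)
        assert res.L == pytest.approx(1.0)
        assert res.interval_low == pytest.approx(1.0)
        assert res.interval_high == pytest.approx(1.0)
        assert not res.significant_sd

    def test_k_formula_against_t_table(self):
        """With r = 0 and n = 42, K = 1 + 2 t^2_{40,0.025} / 40 where the
        tabulated t is 2.021."""
        n = 42
        tcrit = stats.t.ppf(0.975, n - 2)
        assert tcrit == pytest.approx(2.021, abs=5e-4)
        rng = np.random.default_rng(45)
        # construct exactly uncorrelated error vectors
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        ac = a - a.mean()
        b = b - ac * ((ac @ (b - b.mean())) / (ac @ ac))  # residualize
        res = fearn_sd_interval(a, b)
        assert abs(res.r) < 1e-10
        assert res.K == pytest.approx(1 + 2 * tcrit**2 / (n - 2), rel=1e-9)
        assert res.L == pytest.approx(np.sqrt(res.K + np.sqrt(res.K**2 - 1)), rel=1e-12)

    def test_scale_invariance_of_verdict(self):
        rng = np.random.default_rng(46)
        a, b = rng.standard_normal(30), 1.5 * rng.standard_normal(30)
        base = fearn_sd_interval(a, b)
        scaled = fearn_sd_interval(7.3 * a, 7.3 * b)
        assert base.significant_sd == scaled.significant_sd
        assert base.ratio == pytest.approx(scaled.ratio, rel=1e-12)

    def test_swapping_models_inverts_ratio_same_verdict(self):
        rng = np.random.default_rng(47)
        a, b = rng.standard_normal(25), 2.0 * rng.standard_normal(25)
        ab = fearn_sd_interval(a, b)
        ba = fearn_sd_interval(b, a)
        assert ab.ratio == pytest.approx(1.0 / ba.ratio, rel=1e-12)
        assert ab.interval_low == pytest.approx(1.0 / ba.interval_high, rel=1e-12)
        assert ab.significant_sd == ba.significant_sd

    def test_k_at_least_one_and_decreasing_in_r_and_n(self):
        rng = np.random.default_rng(48)
        tgrid = []
        for n in (10, 20, 40, 80):
            for target_r in (0.0, 0.4, 0.8):
                z = rng.standard_normal(n)
                a = z + 0.01 * rng.standard_normal(n)
                b = target_r * z + np.sqrt(max(1 - target_r**2, 1e-6)) * rng.standard_normal(n)
                res = fearn_sd_interval(a, b)
                tgrid.append((n, abs(res.r), res.K))
                assert res.K >= 1.0
        # K computed directly from the formula decreases in |r| and n
        for n in (10, 40):
            tcrit = stats.t.ppf(0.975, n - 2)
            ks = [1 + 2 * (1 - r**2) * tcrit**2 / (n - 2) for r in (0.0, 0.5, 0.9)]
            assert ks == sorted(ks, reverse=True)

    def test_needs_four_pairs(self):
        with pytest.raises(DataValidationError):
            fearn_sd_interval(np.arange(3.0), np.arange(3.0) + 0.5)


class TestComparisonReport:
    def test_identical_error_series_all_ns(self):
        e = np.random.default_rng(49).standard_normal(20)
        report = comparison_report({"moisture_pct": {"a": e, "b": e, "c": e}})
        assert (report["sd_flag"] == "n.s.").all()
        assert (report["bias_flag"] == "n.s.").all()

    def test_row_count_is_responses_times_pairs(self):
        rng = np.random.default_rng(50)
        errors = {
            r: {s: rng.standard_normal(10) for s in ("a", "b", "c")}
            for r in ("moisture_pct", "oil_pct")
        }
        report = comparison_report(errors)
        assert len(report) == 2 * 3  # 2 responses x C(3,2) system pairs

    def test_mismatched_prediction_sets_rejected(self):
        rng = np.random.default_rng(51)
        with pytest.raises(DataValidationError, match="sizes differ"):
            pairwise_sd_comparisons(
                {"a": rng.standard_normal(10), "b": rng.standard_normal(11)}
            )

    def test_inflated_third_system_is_flagged(self):
        """One system with 1.6x the error SD of the other two (n = 80,
        weakly correlated errors) is flagged against both; the equal pair
        is not."""
        rng = np.random.default_rng(52)
        n = 80
        z = rng.standard_normal(n)

        def errs(scale):
            return scale * (np.sqrt(0.3) * z + np.sqrt(0.7) * rng.standard_normal(n))

        report = comparison_report(
            {"oil_pct": {"a": errs(1.0), "b": errs(1.0), "c": errs(1.6)}}
        )
        flags = dict(zip(zip(report.system_a, report.system_b), report.sd_flag))
        assert flags[("a", "b")] == "n.s."
        assert flags[("a", "c")] == "*"
        assert flags[("b", "c")] == "*"
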