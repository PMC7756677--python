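"""Unit tests for the interval engine, anchored on the worked
erythrocyte-comparison numbers (n=20, D̄=-0.012, S=0.047) and on
independent numerical oracles."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from tolagree.intervals import (
    DifferenceSummary,
    agreement_interval,
    agreement_interval_with_cis,
    bg_confidence_of_k,
    bg_tolerance_factor_approx,
    bg_tolerance_factor_exact,
    bg_tolerance_interval,
    bootstrap_t_prediction_interval,
    chisq_quantile,
    normal_quantile,
    prediction_interval,
    sidak_adjust,
    t_quantile,
)


class TestQuantiles:
    @pytest.mark.parametrize(
        "fn, args, expected, tol",
        [
            (normal_quantile, (0.975,), 1.96, 5e-3),     # classic z constant
            (normal_quantile, (0.5,), 0.0, 1e-12),
            (normal_quantile, (0.8,), 0.8416, 5e-5),     # standard-table value
            (t_quantile, (0.975, 19), 2.093, 5e-4),
            (t_quantile, (0.5, 7), 0.0, 1e-12),
            (t_quantile, (0.975, 10**6), 1.960, 1e-3),   # normal limit
            (chisq_quantile, (0.20, 19), 13.716, 5e-4),
        ],
    )
    def test_reference_values(self, fn, args, expected, tol):
        assert fn(*args) == pytest.approx(expected, abs=tol)

    def test_chisq_median_against_numeric_inversion_oracle(self):
        # invert the chi2(1) CDF by integrating its density, no ppf involved
        cdf = lambda x: integrate.quad(lambda t: stats.chi2.pdf(t, 1), 0, x)[0]
        median = optimize.brentq(lambda x: cdf(x) - 0.5, 1e-8, 5.0, xtol=1e-12)
        assert chisq_quantile(0.5, 1) == pytest.approx(median, abs=1e-9)
        assert median == pytest.approx(0.4549, abs=5e-5)

    def test_chisq_monotone_increasing_in_p(self):
        ps = np.linspace(0.01, 0.99, 25)
        qs = [chisq_quantile(p, 19) for p in ps]
        assert np.all(np.diff(qs) > 0)

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_probability_rejected(self, bad_p):
        with pytest.raises(ValueError):
            normal_quantile(bad_p)
        with pytest.raises(ValueError):
            t_quantile(bad_p, 10)
        with pytest.raises(ValueError):
            chisq_quantile(bad_p, 10)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            t_quantile(0.975, 0.5)


class TestDifferenceSummary:
    def test_recomputation_from_vector(self, rng):
        d = rng.normal(0.3, 1.7, size=40)
        s = DifferenceSummary.from_differences(d)
        assert s.n == 40
        assert s.mean_diff == pytest.approx(d.mean(), rel=1e-12)
        assert s.sd_diff == pytest.approx(d.std(ddof=1), rel=1e-12)

    @pytest.mark.parametrize("n, sd", [(1, 1.0), (2, -0.1)])
    def test_invalid_inputs_rejected(self, n, sd):
        with pytest.raises(ValueError):
            DifferenceSummary(n=n, mean_diff=0.0, sd_diff=sd)


class TestAgreementInterval:
    def test_worked_example(self, dog_summary):
        iv = agreement_interval(dog_summary, 0.95)
        assert iv.lower == pytest.approx(-0.1041, abs=5e-5)
        assert iv.upper == pytest.approx(0.0801, abs=5e-5)
        assert round(iv.upper, 3) == 0.080  # printed value

    def test_zero_spread_degenerates_with_warning(self):
        s = DifferenceSummary(10, 0.0, 0.0)
        with pytest.warns(UserWarning):
            iv = agreement_interval(s, 0.95)
        assert iv.lower == iv.upper == 0.0

    def test_symmetry_about_center(self, dog_summary):
        iv = agreement_interval(dog_summary, 0.9)
        assert iv.center - iv.lower == pytest.approx(iv.upper - iv.center, rel=1e-12)


class TestAgreementIntervalWithCIs:
    def test_worked_example_six_values(self, dog_summary):
        iv = agreement_interval_with_cis(dog_summary, 0.95, 0.95)
        assert iv.upper == pytest.approx(0.0801, abs=5e-5)
        lo_ci, hi_ci = iv.ci_upper_bound
        assert lo_ci == pytest.approx(0.0419, abs=5e-5)
        assert hi_ci == pytest.approx(0.1184, abs=5e-5)
        assert round(lo_ci, 3) == 0.042  # printed value
        # printed lower-bound CI {-0.141, -0.065}
        assert iv.ci_lower_bound[0] == pytest.approx(-0.141, abs=2e-3)
        assert iv.ci_lower_bound[1] == pytest.approx(-0.065, abs=2e-3)

    def test_zero_spread_collapses_to_center(self):
        s = DifferenceSummary(10, 1.5, 0.0)
        with pytest.warns(UserWarning):
            iv = agreement_interval_with_cis(s)
        values = [iv.lower, iv.upper, *iv.ci_lower_bound, *iv.ci_upper_bound]
        assert values == pytest.approx([1.5] * 6, abs=1e-15)


class TestPredictionInterval:
    def test_worked_example(self, dog_summary):
        iv = prediction_interval(dog_summary, 0.95)
        assert iv.lower == pytest.approx(-0.1128, abs=5e-5)
        assert iv.upper == pytest.approx(0.0888, abs=5e-5)

    def test_two_subject_case(self):
        iv = prediction_interval(DifferenceSummary(2, 0.0, 1.0), 0.95)
        # t_{0.975,1} = 12.706 times sqrt(3/2)
        assert iv.upper == pytest.approx(12.7062 * math.sqrt(1.5), abs=2e-3)
        assert iv.upper == pytest.approx(15.561, abs=2e-3)

    def test_large_n_converges_to_agreement_interval(self):
        s = DifferenceSummary(10**6, 0.2, 1.3)
        pi = prediction_interval(s, 0.95)
        ai = agreement_interval(s, 0.95)
        assert pi.upper == pytest.approx(ai.upper, rel=1e-5)
        assert pi.lower == pytest.approx(ai.lower, rel=1e-5)


class TestBgFactors:
    def test_approx_worked_example(self, dog_summary):
        f = bg_tolerance_factor_approx(20, 0.95, 0.80)
        # 1.96*sqrt(1.05)*sqrt(19/13.716); half-width 0.047*k = 0.1111
        assert f.k == pytest.approx(2.3641, abs=1e-3)
        assert 0.047 * f.k == pytest.approx(0.1111, abs=1e-4)

    def test_approx_monotone_in_gamma_and_limit_in_n(self):
        ks = [bg_tolerance_factor_approx(20, 0.95, g).k for g in (0.2, 0.5, 0.8, 0.95)]
        assert np.all(np.diff(ks) > 0)
        assert bg_tolerance_factor_approx(10**7, 0.95, 0.8).k == pytest.approx(
            normal_quantile(0.975), rel=1e-3
        )

    def test_exact_matches_independent_quadrature_oracle(self):
        # frozen root of the integral equation computed with adaptive
        # quadrature (scipy.integrate.quad over z, untransformed) + brentq
        assert bg_tolerance_factor_exact(20, 0.95, 0.80).k == pytest.approx(
            2.3654339038776, abs=1e-8
        )
        assert bg_tolerance_factor_exact(50, 0.95, 0.95).k == pytest.approx(
            2.3815597421285, abs=1e-8
        )

    def test_exact_residual_is_tiny(self):
        for n, g in [(5, 0.8), (20, 0.9), (200, 0.95)]:
            k = bg_tolerance_factor_exact(n, 0.95, g).k
            assert abs(bg_confidence_of_k(n, 0.95, k) - g) < 1e-10

    def test_exact_near_approx_for_moderate_n(self):
        for n in (10, 20, 100):
            for g in (0.8, 0.9, 0.95):
                ka = bg_tolerance_factor_approx(n, 0.95, g).k
                ke = bg_tolerance_factor_exact(n, 0.95, g).k
                assert abs(ka / ke - 1) < 0.01

    def test_exact_k_decreasing_in_n_with_normal_limit(self):
        ks = [bg_tolerance_factor_exact(n, 0.95, 0.8).k for n in (5, 10, 50, 500, 10**4)]
        assert np.all(np.diff(ks) < 0)
        assert ks[-1] == pytest.approx(1.96, abs=0.02)

    def test_half_confidence_similar_but_not_equal_to_prediction(self):
        # a beta-expectation TI resembles a beta-gamma TI at 50% confidence
        n = 20
        k = bg_tolerance_factor_exact(n, 0.95, 0.5).k
        c_pi = t_quantile(0.975, n - 1) * math.sqrt(1 + 1 / n)
        assert k == pytest.approx(c_pi, rel=0.06)
        assert k != pytest.approx(c_pi, rel=1e-4)

    def test_nesting_fails_below_the_pi_confidence_level(self):
        # the beta-gamma interval only envelops the prediction interval once
        # gamma exceeds the PI's own effective confidence at that n
        n = 20
        c_pi = t_quantile(0.975, n - 1) * math.sqrt(1 + 1 / n)
        assert bg_tolerance_factor_exact(n, 0.95, 0.60).k < c_pi
        assert bg_tolerance_factor_exact(n, 0.95, 0.80).k > c_pi


class TestBgInterval:
    def test_worked_example_approx(self, dog_summary):
        iv = bg_tolerance_interval(dog_summary, 0.95, 0.80, "bg_approx")
        assert iv.lower == pytest.approx(-0.1231, abs=5e-5)
        assert iv.upper == pytest.approx(0.0991, abs=5e-5)

    def test_higher_confidence_strictly_contains_lower(self, dog_summary):
        a = bg_tolerance_interval(dog_summary, 0.95, 0.8, "bg_exact")
        b = bg_tolerance_interval(dog_summary, 0.95, 0.9, "bg_exact")
        assert b.lower < a.lower < a.upper < b.upper

    def test_zero_spread_degenerate(self):
        with pytest.warns(UserWarning):
            iv = bg_tolerance_interval(DifferenceSummary(8, 0.4, 0.0), 0.95, 0.8, "bg_approx")
        assert iv.lower == iv.upper == 0.4

    def test_unknown_method_rejected(self, dog_summary):
        with pytest.raises(ValueError):
            bg_tolerance_interval(dog_summary, 0.95, 0.8, "bogus")


class TestBootstrapT:
    def test_deterministic_given_seed(self, rng):
        d = rng.normal(0, 1, 30)
        a = bootstrap_t_prediction_interval(d, seed=7)
        b = bootstrap_t_prediction_interval(d, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = bootstrap_t_prediction_interval(d, seed=8)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_large_sample_agrees_with_analytic_interval(self, rng):
        # the empirical pivot quantiles converge to the t quantiles; at
        # moderate n the bounds also track the sample's own tails, so the
        # sharp 10% agreement check needs a genuinely large sample
        d_large = rng.normal(0.5, 2.0, 500)
        boot = bootstrap_t_prediction_interval(d_large, n_boot=4000, seed=11)
        ana = prediction_interval(DifferenceSummary.from_differences(d_large))
        assert boot.lower == pytest.approx(ana.lower, rel=0.10)
        assert boot.upper == pytest.approx(ana.upper, rel=0.10)

    def test_degenerate_resamples_skipped_and_counted(self):
        d = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
        iv = bootstrap_t_prediction_interval(d, n_boot=500, seed=3)
        assert iv.extras["n_skipped"] > 0
        assert np.isfinite(iv.lower) and np.isfinite(iv.upper)

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            bootstrap_t_prediction_interval([1.0, 2.0])
        with pytest.raises(ValueError):
            bootstrap_t_prediction_interval([1.0, 2.0, 3.0], n_boot=50)


class TestSidak:
    @pytest.mark.parametrize(
        "gamma, m, expected, tol",
        [
            (0.90, 3, 0.9655, 5e-5),
            (0.77, 1, 0.77, 1e-15),
            (0.95, 2, 0.974679, 1e-6),
        ],
    )
    def test_values(self, gamma, m, expected, tol):
        assert sidak_adjust(gamma, m) == pytest.approx(expected, abs=tol)

    def test_contracts(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.0, 3)
        with pytest.raises(ValueError):
            sidak_adjust(0.9, 0)
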