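"""Loss-function closed forms against integration and sampling oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import gsdecision as gd
from gsdecision.exceptions import DegenerateTruncationError


def kl_by_integration(mu1, sigma2, yc, mu2):
    """Oracle: KL of the candidate normal from the truncated parent law,
    by numerical integration of the log-density ratio."""
    sd = np.sqrt(sigma2)
    z = stats.norm.sf(yc, mu1, sd)

    def integrand(y):
        log_ft = stats.norm.logpdf(y, mu1, sd) - np.log(z)
        log_fo = stats.norm.logpdf(y, mu2, sd)
        return (log_ft - log_fo) * np.exp(log_ft)

    val, _ = integrate.quad(integrand, yc, mu1 + 14 * sd, limit=200)
    return val


class TestUnivariateKL:
    def test_zero_response_equals_neg_log_z(self):
        s = gd.truncated_normal_summary(0.0, 1.0, 0.0)
        assert gd.kl_univariate(s, 0.0) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_full_response_case(self):
        s = gd.truncated_normal_summary(0.0, 1.0, 0.0)
        v = gd.kl_univariate(s, s.muS)
        assert v == pytest.approx(np.log(2.0) - 0.5 * (2 / np.pi), abs=1e-12)
        assert v == pytest.approx(kl_by_integration(0.0, 1.0, 0.0, s.muS), abs=1e-8)

    def test_matches_integration_oracle_on_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            mu1 = rng.normal(0, 2)
            sigma2 = rng.uniform(0.3, 4.0)
            yc = mu1 + rng.uniform(-2, 2) * np.sqrt(sigma2)
            mu2 = mu1 + rng.normal(0, 1.5)
            s = gd.truncated_normal_summary(mu1, sigma2, yc)
            assert gd.kl_univariate(s, mu2) == pytest.approx(
                kl_by_integration(mu1, sigma2, yc, mu2), abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(mu1=st.floats(-3, 3), sig=st.floats(0.3, 3.0),
           d=st.floats(-2, 2), r=st.floats(-2, 2))
    def test_three_algebraic_forms_agree(self, mu1, sig, d, r):
        """Mean form, (S, R) form and heritability form are identities."""
        yc = mu1 + sig * d
        s = gd.truncated_normal_summary(mu1, sig**2, yc)
        for h2 in (0.0, 0.3, 0.6, 1.0):
            mu2 = mu1 + h2 * s.S
            v_mean = gd.kl_univariate(s, mu2)
            v_sr = gd.kl_univariate_sr(s.S, h2 * s.S, s.sigma2, s.z)
            v_h2 = gd.kl_univariate_h2(s.i, h2, s.z)
            assert v_mean == pytest.approx(v_sr, abs=1e-12)
            assert v_mean == pytest.approx(v_h2, abs=1e-12)
        # arbitrary mu2 as well for the (S, R) form
        mu2 = mu1 + r
        assert gd.kl_univariate(s, mu2) == pytest.approx(
            gd.kl_univariate_sr(s.S, r, s.sigma2, s.z), abs=1e-12)

    def test_h2_edge_values(self):
        assert gd.kl_univariate_h2(0.8, 0.0, 0.5) == pytest.approx(np.log(2.0))
        assert gd.kl_univariate_h2(0.0, 0.7, 0.5) == pytest.approx(np.log(2.0))

    def test_decreasing_in_h2(self):
        for i in (0.5, 1.0, 1.755):
            vals = [gd.kl_univariate_h2(i, h2, 0.5) for h2 in np.linspace(0, 1, 21)]
            assert np.all(np.diff(vals) < 0)

    def test_degenerate_z(self):
        s = gd.TruncationSummary(mu1=0, sigma2=1, yc=0, z=0.0, muS=0.8, S=0.8, i=0.8)
        with pytest.raises(DegenerateTruncationError):
            gd.kl_univariate(s, 0.0)


class TestCRPS:
    def test_zero_deviation_value(self):
        s = gd.truncated_normal_summary(0.0, 1.0, 0.0)
        v = gd.crps_univariate(s, s.muS)
        # phi(0) and Phi(0) re-derived from the standard normal density
        phi0 = 1.0 / np.sqrt(2 * np.pi)
        assert v == pytest.approx(-(1 / np.pi - 2 * phi0), abs=1e-12)
        assert v == pytest.approx(0.47958, abs=1e-5)

    def test_tail_limit(self):
        s = gd.truncated_normal_summary(0.0, 1.0, 0.0)
        e = 30.0
        assert gd.crps_univariate(s, s.muS - e) == pytest.approx(e - 1 / np.pi, abs=1e-6)

    @settings(derandomize=True, max_examples=40)
    @given(d=st.floats(-2, 2), h2=st.floats(0, 1), sig=st.floats(0.3, 3))
    def test_h2_form_equals_parameter_form(self, d, h2, sig):
        s = gd.truncated_normal_summary(1.0, sig**2, 1.0 + sig * d)
        mu2 = s.mu1 + h2 * s.S  # R = h2 S, so e = sigma i (1 - h2)
        assert gd.crps_univariate(s, mu2) == pytest.approx(
            gd.crps_univariate_h2(s.i, h2, sig), abs=1e-12)

    def test_h2_one_equals_zero_deviation(self):
        assert gd.crps_univariate_h2(0.9, 1.0) == pytest.approx(
            gd.crps_univariate_h2(0.0, 0.3), abs=1e-12)

    def test_decreasing_in_h2(self):
        for i in (0.4, 1.0, 1.755):
            vals = [gd.crps_univariate_h2(i, h2) for h2 in np.linspace(0, 1, 21)]
            assert np.all(np.diff(vals) < 0)

    def test_standard_constant_option(self):
        v_paper = gd.crps_univariate_h2(0.0, 0.5, constant="paper")
        v_std = gd.crps_univariate_h2(0.0, 0.5, constant="standard")
        assert v_std - v_paper == pytest.approx(1 / np.pi - 1 / np.sqrt(np.pi), abs=1e-12)
        # the standard constant gives the textbook CRPS of N(0,1) vs its mean
        assert v_std == pytest.approx(np.sqrt(2 / np.pi) - 1 / np.sqrt(np.pi), abs=1e-12)


class TestLinLin:
    @pytest.mark.parametrize("e,alpha,expected", [
        (2.0, 0.9, 1.8),
        (-2.0, 0.9, 0.2),
        (2.0, 0.5, 1.0),
        (-2.0, 0.5, 1.0),
    ])
    def test_branches(self, e, alpha, expected):
        assert gd.linlin(e, alpha) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=40)
    @given(e=st.floats(0.01, 10), alpha=st.floats(0.51, 0.99))
    def test_asymmetry_penalizes_undershoot(self, e, alpha):
        assert gd.linlin(e, alpha) > gd.linlin(-e, alpha)
        assert gd.linlin(e, alpha) >= 0 and gd.linlin(-e, alpha) >= 0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            gd.linlin(1.0, 1.2)


class TestMultivariateKL:
    def test_identical_distributions_zero(self):
        P = np.array([[1.5, 0.3], [0.3, 1.0]])
        s = gd.mv_truncation_summary([0.0, 0.0], P, [-np.inf, -np.inf])
        assert s.z == pytest.approx(1.0)
        assert gd.kl_multivariate(s, s.mu1) == pytest.approx(0.0, abs=1e-10)
        assert gd.kl_multivariate_h2(np.zeros(2), P, P, 1.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("h2", [0.0, 0.3, 0.6, 1.0])
    def test_univariate_reduction(self, h2):
        s = gd.truncated_normal_summary(0.0, 1.0, 0.0)
        v = gd.kl_multivariate_h2(np.array([s.S]), np.array([[1.0]]),
                                  np.array([[h2]]), s.z)
        assert v == pytest.approx(gd.kl_univariate_h2(s.i, h2, s.z), abs=1e-12)

    def test_h2_form_equals_mean_form_under_breeders_equation(self):
        P = np.array([[2.0, 0.5], [0.5, 1.2]])
        G = np.array([[1.0, 0.2], [0.2, 0.7]])
        s = gd.mv_truncation_summary([1.0, -0.5], P, [1.5, -0.3])
        mu2 = s.mu1 + G @ np.linalg.solve(P, s.S)
        assert gd.kl_multivariate(s, mu2) == pytest.approx(
            gd.kl_multivariate_h2(s.S, P, G, s.z), abs=1e-10)

    def test_against_mc_log_ratio_oracle(self):
        """Average log-density ratio over rejection samples from the TMVN."""
        P = np.array([[1.0, 0.4], [0.4, 1.0]])
        mu1 = np.zeros(2)
        yc = np.array([0.3, -0.2])
        s = gd.mv_truncation_summary(mu1, P, yc)
        mu2 = np.array([0.5, 0.1])
        closed = gd.kl_multivariate(s, mu2)

        rng = np.random.default_rng(11)
        draws = rng.multivariate_normal(mu1, P, size=2_000_000)
        kept = draws[np.all(draws >= yc, axis=1)]
        log_ft = stats.multivariate_normal(mu1, P).logpdf(kept) - np.log(s.z)
        log_fo = stats.multivariate_normal(mu2, P).logpdf(kept)
        ratios = log_ft - log_fo
        mc, se = ratios.mean(), ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert closed == pytest.approx(mc, abs=max(3 * se, 1e-4))


class TestEnergyScore:
    def test_point_mass_is_zero(self):
        draws = np.tile([1.0, 2.0], (10, 1))
        assert gd.energy_score(draws, [1.0, 2.0]) == 0.0

    def test_univariate_closed_form_convergence(self):
        rng = np.random.default_rng(13)
        sigma = 1.7
        m = 100_000
        draws = rng.normal(3.0, sigma, size=(m, 1))
        est = gd.energy_score(draws, [3.0])
        expected = sigma * (2 * stats.norm.pdf(0) - 1 / np.sqrt(np.pi))
        # conservative MC standard error of the two averaged terms
        se = sigma * np.sqrt(1.0 / m + 1.0 / (m // 2))
        assert est == pytest.approx(expected, abs=3 * se)

    def test_translation_invariance(self):
        rng = np.random.default_rng(17)
        draws = rng.normal(size=(500, 3))
        shift = np.array([5.0, -2.0, 0.4])
        v1 = gd.energy_score(draws, np.zeros(3))
        v2 = gd.energy_score(draws + shift, shift)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_error_shrinks_with_draw_count(self):
        rng = np.random.default_rng(19)
        expected = 2 * stats.norm.pdf(0) - 1 / np.sqrt(np.pi)
        errs = []
        for m in (200, 20_000):
            reps = [abs(gd.energy_score(rng.normal(size=(m, 1)), [0.0]) - expected)
                    for _ in range(10)]
            errs.append(np.mean(reps))
        assert errs[1] < errs[0] / 3  # ~10x draws -> ~3x smaller error

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            gd.energy_score(np.array([[1.0]]), [0.0])


class TestMALF:
    def test_zero_deviation(self):
        assert gd.malf(np.zeros(3), np.full(3, 0.7), "l2") == 0.0
        assert gd.malf(np.zeros(3), np.full(3, 0.7), "l1") == 0.0

    def test_univariate_l1_is_twice_linlin(self):
        for e in (-3.0, -0.4, 0.4, 2.0):
            for alpha in (0.6, 0.7, 0.9):
                tau = 2 * alpha - 1
                assert gd.malf([e], [tau], "l1") == pytest.approx(
                    2 * gd.linlin(e, alpha), abs=1e-12)

    def test_symmetric_l2_is_squared_norm(self):
        assert gd.malf([3.0, 4.0], [0.0, 0.0], "l2") == pytest.approx(25.0)

    def test_l1_hand_value(self):
        assert gd.malf([2.0], [0.8], "l1") == pytest.approx(3.6)

    def test_warns_on_large_tau(self):
        with pytest.warns(UserWarning):
            gd.malf([1.0, -1.0], [1.5, 0.0], "l2")
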