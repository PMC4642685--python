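import numpy as np
import pytest

from undx import core, direct, forward
from undx.core import RateSet, RateSurface
from undx.direct import CrossSection, EstimateFlag


def _cs(t, ages, p1, p2):
    ages = np.asarray(ages, dtype=float)
    return CrossSection(t=t, ages=ages,
                        p1=np.broadcast_to(np.asarray(p1, float), ages.shape),
                        p2=np.broadcast_to(np.asarray(p2, float), ages.shape))


def _affine_cs(t, ages, alpha, beta):
    ages = np.asarray(ages, dtype=float)
    val = alpha * t + beta * ages
    return CrossSection(t=t, ages=ages, p1=val, p2=val / 2)


class TestCrossSection:
    def test_validation(self):
        with pytest.raises(core.DomainError):
            _cs(0.0, [50, 60], 0.6, 0.5)
        with pytest.raises(core.ConfigurationError):
            CrossSection(t=0.0, ages=[60, 50], p1=[0.1, 0.1], p2=[0.1, 0.1])

    def test_binomial_se_fill_from_n(self):
        cs = CrossSection(t=0.0, ages=[50.0, 60.0], p1=[0.1, 0.2],
                          p2=[0.0, 0.1], n=[100, 400])
        assert cs.se1[0] == pytest.approx(np.sqrt(0.1 * 0.9 / 100))
        assert cs.se2[1] == pytest.approx(np.sqrt(0.1 * 0.9 / 400))

    def test_out_of_support_interp_raises(self):
        cs = _cs(0.0, [50, 60], 0.1, 0.1)
        with pytest.raises(core.SupportError, match="49"):
            cs.p1_at(49.0)


class TestCharacteristicDerivative:
    def test_constant_field_gives_zero(self):
        d1, d2 = direct.characteristic_derivative(
            _cs(99.0, np.arange(50, 70.0), 0.2, 0.1),
            _cs(101.0, np.arange(50, 70.0), 0.2, 0.1), 100.0, [55.0, 60.0])
        assert np.allclose(d1, 0) and np.allclose(d2, 0)

    def test_affine_field_exact(self):
        alpha, beta = 1e-3, 2e-3
        d1, d2 = direct.characteristic_derivative(
            _affine_cs(99.0, np.arange(40, 80.0), alpha, beta),
            _affine_cs(101.0, np.arange(40, 80.0), alpha, beta),
            100.0, [60.0])
        assert d1[0] == pytest.approx(alpha + beta, rel=1e-12)
        assert d2[0] == pytest.approx((alpha + beta) / 2, rel=1e-12)

    def test_matches_pde_rhs_on_forward_solution(self, scenario_rates,
                                                 scenario_waves, inverse_ages,
                                                 p_at_tprime):
        cs1, cs2 = scenario_waves
        # stop short of age 100, where the incidence table's slope break
        # makes the finite difference locally first-order
        inverse_ages = inverse_ages[:-1]
        d1, d2 = direct.characteristic_derivative(cs1, cs2, 100.0, inverse_ages)
        p1 = p_at_tprime[0][:-1]
        p2 = p_at_tprime[1][:-1]
        t = np.full_like(inverse_ages, 100.0)
        f1, f2 = forward.pde_rhs(
            scenario_rates.lambda0(t, inverse_ages),
            scenario_rates.lambda1(t, inverse_ages),
            scenario_rates.mu(t, inverse_ages),
            scenario_rates.mu1(t, inverse_ages),
            scenario_rates.mu2(t, inverse_ages), p1, p2)
        # second-order accurate in (t2 - t1) = 2 years
        assert np.max(np.abs(d1 - f1)) < 3e-4
        assert np.max(np.abs(d2 - f2)) < 3e-4


class TestRateFormulas:
    def test_lambda1_stationary_neutral(self):
        lam1, flags = direct.estimate_lambda1(0.3, 0.2, 0.0, 0.02, 0.02)
        assert lam1 == pytest.approx(0.0)
        assert flags == EstimateFlag.OK

    def test_lambda1_hand_value(self):
        lam1, _ = direct.estimate_lambda1(p1=0.1, p2=0.2, deriv2=0.01,
                                          mu=0.0, mu2=0.005)
        assert lam1 == pytest.approx(0.11)

    def test_lambda1_negative_flagged_not_raised(self):
        lam1, flags = direct.estimate_lambda1(0.1, 0.2, -0.05, 0.02, 0.02)
        assert lam1 < 0
        assert flags & EstimateFlag.NEGATIVE_LAMBDA1

    def test_lambda1_undefined_when_p1_empty(self):
        lam1, flags = direct.estimate_lambda1(0.0, 0.2, 0.01, 0.02, 0.02)
        assert np.isnan(lam1)
        assert flags & EstimateFlag.P1_TOO_SMALL

    def test_lambda0_no_undiagnosed_pool(self):
        lam0, _ = direct.estimate_lambda0(p1=0.0, p2=0.3, deriv1=0.0,
                                          lambda1=0.5, mu=0.02, mu1=0.06)
        assert lam0 == pytest.approx(0.0)

    def test_lambda0_hand_value(self):
        lam0, _ = direct.estimate_lambda0(p1=0.1, p2=0.2, deriv1=0.002,
                                          lambda1=0.11, mu=0.0, mu1=0.01)
        assert lam0 == pytest.approx(0.02)

    def test_lambda0_undefined_when_healthy_pool_empty(self):
        lam0, flags = direct.estimate_lambda0(0.6, 0.4, 0.0, 0.1, 0.02, 0.02)
        assert np.isnan(lam0)
        assert flags & EstimateFlag.P0_TOO_SMALL


def _smooth_rates(k):
    """Three distinct smooth rate sets for round-trip studies."""
    mu = RateSurface(fn=lambda t, a: np.exp(-9.0 + 0.08 * a + 0.001 * t))
    lam0 = RateSurface(fn=lambda t, a, _k=k: (0.005 + 0.0004 * _k * a)
                       / (1 + np.exp(-(a - 50.0) / 8.0)))
    lam1 = RateSurface(fn=lambda t, a, _k=k: (0.05 + 0.01 * _k)
                       * (1 + 0.3 * np.sin(a / 15.0)) * (1 + 0.002 * t))
    return RateSet(lambda0=lam0, lambda1=lam1, mu=mu,
                   mu1=mu.scaled(2.0 + 0.5 * k), mu2=mu.scaled(1.5))


class TestDirectInverse:
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_roundtrip_error_first_order_in_wave_gap(self, k):
        """Forward -> direct-inverse recovers the rates, with error
        vanishing as the waves move together."""
        rates = _smooth_rates(k)
        t_prime = 100.0
        ages = np.arange(60.0, 91.0)
        tvec = np.full_like(ages, t_prime)
        true0 = rates.lambda0(tvec, ages)
        true1 = rates.lambda1(tvec, ages)
        errs = {}
        for gap in (4.0, 2.0, 1.0):
            # tabulate at half-year ages so every shifted age is a node
            tab = np.arange(50.0, 100.0, 0.5)
            cs1 = forward.cross_section_at(rates, t_prime - gap / 2, tab)
            cs2 = forward.cross_section_at(rates, t_prime + gap / 2, tab)
            p_exact = forward.prevalence_at(rates, t_prime, ages)
            est = direct.direct_inverse(cs1, cs2, mu=rates.mu, mu1=rates.mu1,
                                        mu2=rates.mu2, t_prime=t_prime,
                                        ages=ages, p_tprime=p_exact)
            errs[gap] = max(np.max(np.abs(est.lambda0 - true0) / true0),
                            np.max(np.abs(est.lambda1 - true1) / true1))
        assert errs[2.0] < 0.75 * errs[4.0]
        assert errs[1.0] < 0.75 * errs[2.0]
        assert errs[1.0] < 0.01

    def test_mortality_level_shift_invariance(self, scenario_waves,
                                              inverse_ages, p_at_tprime):
        """Only the differences mu1 - mu and mu2 - mu matter."""
        cs1, cs2 = scenario_waves
        ages = inverse_ages
        base_mu = 0.02 * np.ones_like(ages)
        mu1 = 0.05 * np.ones_like(ages)
        mu2 = 0.04 * np.ones_like(ages)
        a = direct.direct_inverse(cs1, cs2, mu=base_mu, mu1=mu1, mu2=mu2,
                                  t_prime=100.0, ages=ages,
                                  p_tprime=p_at_tprime)
        shift = 0.013
        b = direct.direct_inverse(cs1, cs2, mu=base_mu + shift,
                                  mu1=mu1 + shift, mu2=mu2 + shift,
                                  t_prime=100.0, ages=ages,
                                  p_tprime=p_at_tprime)
        assert np.allclose(a.lambda0, b.lambda0, rtol=1e-9)
        assert np.allclose(a.lambda1, b.lambda1, rtol=1e-9)

    def test_exact_derivatives_cut_errors_tenfold(self, scenario_rates,
                                                  scenario_waves, inverse_ages,
                                                  scenario_truth, p_at_tprime):
        """Replacing the two-wave finite difference by the analytic
        transport-equation derivative isolates the linearisation error."""
        cs1, cs2 = scenario_waves
        ages = inverse_ages
        true0, true1 = scenario_truth
        p1, p2 = p_at_tprime
        t = np.full_like(ages, 100.0)
        mu = scenario_rates.mu(t, ages)
        mu1 = scenario_rates.mu1(t, ages)
        mu2 = scenario_rates.mu2(t, ages)

        est_fd = direct.direct_inverse(cs1, cs2, mu=mu, mu1=mu1, mu2=mu2,
                                       t_prime=100.0, ages=ages,
                                       p_tprime=(p1, p2))
        f1, f2 = forward.pde_rhs(true0, true1, mu, mu1, mu2, p1, p2)
        lam1_exact, _ = direct.estimate_lambda1(p1, p2, f2, mu, mu2)
        lam0_exact, _ = direct.estimate_lambda0(p1, p2, f1, lam1_exact, mu, mu1)

        err_fd = max(np.max(np.abs(est_fd.lambda0 - true0) / true0),
                     np.max(np.abs(est_fd.lambda1 - true1) / true1))
        err_exact = max(np.max(np.abs(lam0_exact - true0) / true0),
                        np.max(np.abs(lam1_exact - true1) / true1))
        assert err_exact < err_fd / 10

    def test_sanitized_view_clamps_negatives(self):
        est = direct.IncidenceEstimate(
            t_prime=0.0, ages=np.array([60.0]), lambda0=np.array([-0.01]),
            lambda1=np.array([0.2]), flags=np.array([8]))
        san = est.sanitized()
        assert san.lambda0[0] == 0.0
        assert est.lambda0[0] == -0.01  # raw view untouched
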