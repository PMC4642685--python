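import numpy as np
import pytest

from undx import core, direct, forward, leastsq, scenario
from undx.direct import CrossSection
from undx.leastsq import (LSProblem, MortalityRiskTerm, UncertainValues,
                          fit_rates, log_dr_uncertainty, midpoint_prevalence,
                          objective_x2, predict_cross_sections, run_psa)


def _cs(t, ages, p1, p2, **kw):
    ages = np.asarray(ages, dtype=float)
    return CrossSection(t=t, ages=ages,
                        p1=np.broadcast_to(np.asarray(p1, float), ages.shape),
                        p2=np.broadcast_to(np.asarray(p2, float), ages.shape),
                        **kw)


@pytest.fixture(scope="module")
def scenario_problem(scenario_waves, inverse_ages):
    rates = scenario.build_scenario()
    cs1, cs2 = scenario_waves
    return LSProblem(cs1=cs1, cs2=cs2, mu=rates.mu, mu1=rates.mu1,
                     mu2=rates.mu2, t_prime=100.0, knots=inverse_ages,
                     eval_ages=inverse_ages, sigma_mode="unit")


class TestMidpointPrevalence:
    def test_symmetric_weights_average(self):
        ages = np.arange(50.0, 70.0)
        cs1 = CrossSection(t=99.0, ages=ages, p1=0.2 + 0.001 * ages,
                           p2=np.full_like(ages, 0.1))
        cs2 = CrossSection(t=101.0, ages=ages, p1=0.3 + 0.001 * ages,
                           p2=np.full_like(ages, 0.2))
        p1, p2 = midpoint_prevalence(cs1, cs2, 100.0, np.array([60.0]))
        expect = 0.5 * (cs1.p1_at(59.0) + cs2.p1_at(61.0))
        assert p1[0] == pytest.approx(expect, rel=1e-12)
        assert p2[0] == pytest.approx(0.15, rel=1e-12)

    def test_constant_field_returned_unchanged(self):
        ages = np.arange(50.0, 70.0)
        p1, p2 = midpoint_prevalence(_cs(99.0, ages, 0.17, 0.05),
                                     _cs(101.0, ages, 0.17, 0.05),
                                     100.0, np.array([55.0, 60.0]))
        assert np.allclose(p1, 0.17) and np.allclose(p2, 0.05)

    def test_close_to_forward_solution_on_scenario(self, scenario_waves,
                                                   inverse_ages, p_at_tprime):
        cs1, cs2 = scenario_waves
        p1, p2 = midpoint_prevalence(cs1, cs2, 100.0, inverse_ages)
        # O(h1*h2) accuracy with h1 = h2 = 1 year
        assert np.max(np.abs(p1 - p_at_tprime[0])) < 2e-3
        assert np.max(np.abs(p2 - p_at_tprime[1])) < 2e-3


class TestPredictions:
    def test_frozen_dynamics_shift_unchanged(self):
        ages = np.arange(50.0, 70.0)
        cs1 = _cs(99.0, ages, 0.12, 0.3)
        cs2 = _cs(101.0, ages, 0.12, 0.3)
        prob = LSProblem(cs1=cs1, cs2=cs2, mu=0.02, mu1=0.02, mu2=0.02,
                         sigma_mode="unit")
        zero = np.zeros(len(prob.knots))
        pred = predict_cross_sections(prob, zero, zero)
        assert np.allclose(pred[("w1", 1)], 0.12)
        assert np.allclose(pred[("w2", 2)], 0.3)

    def test_truth_predicts_waves_second_order(self, scenario_problem,
                                               scenario_truth):
        pred = predict_cross_sections(scenario_problem, *scenario_truth)
        ws = leastsq._Workspace(scenario_problem)
        for key in ws.obs:
            err = np.abs(pred[key] - ws.obs[key])
            # interior ages are smooth; the final age sits on the incidence
            # table's slope break where the local error order drops
            assert np.max(err[:-1]) < 5e-4
            assert np.max(err) < 2e-3

    def test_negative_guess_rejected(self, scenario_problem):
        n = len(scenario_problem.knots)
        with pytest.raises(core.DomainError):
            predict_cross_sections(scenario_problem, -np.ones(n), np.ones(n))


class TestObjective:
    def test_zero_at_perfect_fit(self):
        ages = np.arange(50.0, 70.0)
        cs1 = _cs(99.0, ages, 0.12, 0.3)
        cs2 = _cs(101.0, ages, 0.12, 0.3)
        prob = LSProblem(cs1=cs1, cs2=cs2, mu=0.02, mu1=0.02, mu2=0.02,
                         sigma_mode="unit")
        zero = np.zeros(len(prob.knots))
        assert objective_x2(prob, zero, zero) == pytest.approx(0.0, abs=1e-20)

    def test_sigma_scaling_homogeneity(self, scenario_waves):
        cs1, cs2 = scenario_waves
        rates = scenario.build_scenario()
        knots = np.arange(80.0, 91.0)
        guess0 = np.full(len(knots), 0.05)
        guess1 = np.full(len(knots), 0.3)
        vals = {}
        for c in (1.0, 2.0):
            se = [np.full(cs.ages.shape, 0.01 * c) for cs in (cs1, cs2)]
            w1 = CrossSection(t=cs1.t, ages=cs1.ages, p1=cs1.p1, p2=cs1.p2,
                              se1=se[0], se2=se[0])
            w2 = CrossSection(t=cs2.t, ages=cs2.ages, p1=cs2.p1, p2=cs2.p2,
                              se1=se[1], se2=se[1])
            prob = LSProblem(cs1=w1, cs2=w2, mu=rates.mu, mu1=rates.mu1,
                             mu2=rates.mu2, t_prime=100.0, knots=knots,
                             eval_ages=knots, sigma_mode="se")
            vals[c] = objective_x2(prob, guess0, guess1)
        assert vals[2.0] == pytest.approx(vals[1.0] / 4.0, rel=1e-12)

    def test_single_residual_standardisation(self):
        ages = np.array([59.0, 60.0, 61.0])
        cs1 = CrossSection(t=99.0, ages=ages, p1=[0.1, 0.1, 0.1],
                           p2=[0.0, 0.0, 0.0],
                           se1=[0.02] * 3, se2=[0.05] * 3)
        cs2 = CrossSection(t=101.0, ages=ages, p1=[0.1, 0.1, 0.1],
                           p2=[0.0, 0.0, 0.0],
                           se1=[0.02] * 3, se2=[0.05] * 3)
        prob = LSProblem(cs1=cs1, cs2=cs2, mu=0.0, mu1=0.0, mu2=0.0,
                         knots=np.array([60.0]), eval_ages=np.array([60.0]),
                         sigma_mode="se")
        # lambda1 * p1 = 0.02 drains p1 (sigma 0.02 -> unit residuals) and
        # feeds p2 (sigma 0.05): X^2 = 2*1^2 + 2*(0.02/0.05)^2
        x2 = objective_x2(prob, np.array([0.0]), np.array([0.2]))
        assert x2 == pytest.approx(2 + 2 * (0.02 / 0.05) ** 2, rel=1e-12)

    def test_zero_sigma_rejected(self):
        ages = np.array([59.0, 60.0, 61.0])
        cs = CrossSection(t=99.0, ages=ages, p1=[0.1] * 3, p2=[0.0] * 3,
                          se1=[0.0] * 3, se2=[0.01] * 3)
        cs2 = CrossSection(t=101.0, ages=ages, p1=[0.1] * 3, p2=[0.0] * 3,
                           se1=[0.01] * 3, se2=[0.01] * 3)
        prob = LSProblem(cs1=cs, cs2=cs2, mu=0.0, mu1=0.0, mu2=0.0,
                         knots=np.array([60.0]), eval_ages=np.array([60.0]),
                         sigma_mode="se")
        with pytest.raises(core.ConfigurationError):
            objective_x2(prob, np.array([0.0]), np.array([0.0]))


class TestFit:
    def test_objective_at_estimate_beats_truth(self, scenario_problem,
                                               scenario_truth):
        est = fit_rates(scenario_problem)
        x2_est = objective_x2(scenario_problem, np.maximum(est.lambda0, 0),
                              np.maximum(est.lambda1, 0))
        x2_truth = objective_x2(scenario_problem, *scenario_truth)
        assert x2_est <= x2_truth + 1e-12

    def test_matches_direct_route_on_noise_free_waves(self, scenario_waves,
                                                      inverse_ages):
        """With equal weights the least-squares solution coincides with the
        closed-form solution evaluated at the midpoint prevalences."""
        rates = scenario.build_scenario()
        cs1, cs2 = scenario_waves
        prob = LSProblem(cs1=cs1, cs2=cs2, mu=rates.mu, mu1=rates.mu1,
                         mu2=rates.mu2, t_prime=100.0, knots=inverse_ages,
                         eval_ages=inverse_ages, sigma_mode="unit")
        est_ls = fit_rates(prob)
        est_direct = direct.direct_inverse(cs1, cs2, mu=rates.mu,
                                           mu1=rates.mu1, mu2=rates.mu2,
                                           t_prime=100.0, ages=inverse_ages)
        assert np.allclose(est_ls.lambda0, est_direct.lambda0, rtol=1e-6)
        assert np.allclose(est_ls.lambda1, est_direct.lambda1, rtol=1e-6)

    def test_standardised_residuals_are_standard_normal(self):
        """On correctly specified noisy data the standardised residuals at
        the optimum behave like N(0, 1)."""
        rates = scenario.diabetes_like_rates()
        ages = np.arange(50.0, 96.0)
        rng = np.random.default_rng(7)
        cs1 = scenario.synth_cross_section(rates, 106.0, ages, 50_000, rng)
        cs2 = scenario.synth_cross_section(rates, 108.0, ages, 50_000, rng)
        prob = LSProblem(cs1=cs1, cs2=cs2, mu=rates.mu, mu1=rates.mu1,
                         mu2=rates.mu2, knots=np.arange(54.0, 87.0, 8.0),
                         eval_ages=np.arange(54.0, 87.0), sigma_mode="se")
        est = fit_rates(prob)
        ws = leastsq._Workspace(prob)
        r = ws.residuals(leastsq._pack(prob, est.lambda0, est.lambda1, None))
        assert abs(np.mean(r)) < 0.3
        assert 0.6 < np.std(r) < 1.4


def _tiny_problem(se_scale=0.0, n=None):
    """Small synthetic problem with optional prevalence uncertainty."""
    rates = scenario.diabetes_like_rates()
    ages = np.arange(58.0, 75.0)
    p = [forward.prevalence_at(rates, t, ages) for t in (106.0, 108.0)]
    kw = {}
    waves = []
    for (p1, p2), t in zip(p, (106.0, 108.0)):
        se = np.full_like(ages, 0.004 * se_scale) if se_scale else None
        waves.append(CrossSection(t=t, ages=ages, p1=p1, p2=p2,
                                  se1=se, se2=se, **kw))
    return LSProblem(cs1=waves[0], cs2=waves[1], mu=rates.mu, mu1=rates.mu1,
                     mu2=rates.mu2, knots=np.array([62.0, 66.0, 70.0]),
                     eval_ages=np.arange(62.0, 71.0),
                     sigma_mode="se" if se_scale else "unit")


class TestPSA:
    def test_degenerate_distributions_give_zero_sd(self):
        psa = run_psa(_tiny_problem(se_scale=0.0), n_draws=5, seed=3)
        assert np.all(psa.sd_lambda0 == 0)
        assert np.all(psa.sd_lambda1 == 0)

    def test_same_seed_bitwise_identical(self):
        prob = _tiny_problem(se_scale=1.0)
        a = run_psa(prob, n_draws=12, seed=11)
        b = run_psa(prob, n_draws=12, seed=11)
        assert np.array_equal(a.lambda0_draws, b.lambda0_draws)
        assert np.array_equal(a.lambda1_draws, b.lambda1_draws)

    def test_sd_grows_with_input_uncertainty(self):
        sds = []
        for scale in (1.0, 2.0, 4.0):
            psa = run_psa(_tiny_problem(se_scale=scale), n_draws=60, seed=5)
            sds.append(np.mean(psa.sd_lambda0) + np.mean(psa.sd_lambda1))
        assert sds[0] < sds[1] < sds[2]

    def test_summaries_recomputable_from_draws(self):
        psa = run_psa(_tiny_problem(se_scale=1.0), n_draws=20, seed=9)
        ok = psa.ok
        assert np.allclose(psa.mean_lambda0,
                           psa.lambda0_draws[ok].mean(axis=0))
        assert np.allclose(psa.sd_lambda1,
                           psa.lambda1_draws[ok].std(axis=0, ddof=1))


class TestLogDR:
    def _psa_from_draws(self, l0, l1):
        n, k = l0.shape
        base = direct.IncidenceEstimate(
            t_prime=0.0, ages=np.arange(k, dtype=float),
            lambda0=l0.mean(axis=0), lambda1=l1.mean(axis=0),
            flags=np.zeros(k, dtype=int))
        return leastsq.PSAResult(ages=np.arange(k, dtype=float),
                                 lambda0_draws=l0, lambda1_draws=l1,
                                 r_draws=None, ok=np.ones(n, dtype=bool),
                                 seed=0, base=base)

    def test_proportional_rates_give_constant_log_dr(self):
        rng = np.random.default_rng(1)
        l0 = rng.uniform(0.01, 0.1, size=(40, 3))
        psa = self._psa_from_draws(l0, 5.0 * l0)
        out = log_dr_uncertainty(psa)
        assert np.allclose(out.mean_log_dr, np.log(5.0))
        assert np.allclose(out.sd_log_dr, 0.0, atol=1e-12)

    def test_variance_formula_matches_empirical(self):
        rng = np.random.default_rng(2)
        l0 = rng.lognormal(-3.5, 0.4, size=(200, 4))
        l1 = rng.lognormal(-1.5, 0.6, size=(200, 4)) * np.sqrt(l0)
        out = log_dr_uncertainty(self._psa_from_draws(l0, l1))
        assert np.max(np.abs(out.sd_log_dr - out.sd_log_dr_empirical)) < 1e-12

    def test_boundary_zero_draws_excluded(self):
        l0 = np.array([[0.02], [0.03], [0.025]])
        l1 = np.array([[0.2], [0.0], [0.3]])
        with pytest.warns(RuntimeWarning):
            out = log_dr_uncertainty(self._psa_from_draws(l0, l1))
        assert out.n_used[0] == 2
        assert out.n_excluded[0] == 1


class TestMortalityRiskTerm:
    def test_r_recovered_from_exact_proportional_risk(self):
        """When the undiagnosed mortality risk is exactly R times the
        general risk and the waves were generated with mu1 = R * mu, the
        joint fit recovers R and the rates."""
        r_true = 2.2
        base = scenario.diabetes_like_rates()
        mu = base.mu
        rates = core.RateSet(lambda0=base.lambda0, lambda1=base.lambda1,
                             mu=mu, mu1=mu.scaled(r_true), mu2=base.mu2)
        ages = np.arange(50.0, 96.0)
        cs1 = forward.cross_section_at(rates, 106.0, ages)
        cs2 = forward.cross_section_at(rates, 108.0, ages)
        ages_m = np.arange(55.0, 90.0)
        pi = mu(np.full_like(ages_m, 107.0), ages_m)  # any proportional proxy
        term = MortalityRiskTerm(ages=ages_m, pm=r_true * pi,
                                 sigma_m=np.full_like(ages_m, 1e-4), pi=pi)
        knots = np.arange(54.0, 87.0, 8.0)
        prob = LSProblem(cs1=cs1, cs2=cs2, mu=mu, mu1=None, mu2=rates.mu2,
                         knots=knots, eval_ages=np.arange(54.0, 87.0),
                         sigma_mode="unit", mortality_risk=term)
        est = fit_rates(prob)
        assert est.meta["R"] == pytest.approx(r_true, rel=1e-3)
        truth0 = rates.lambda0(np.full_like(knots, 107.0), knots)
        assert np.allclose(est.lambda0, truth0, rtol=0.05)

    def test_uncertain_values_interpolation(self):
        uv = UncertainValues(ages=[50.0, 60.0], values=[0.1, 0.3])
        assert uv.at(55.0) == pytest.approx(0.2)
        assert uv.at(40.0) == pytest.approx(0.1)  # constant extrapolation
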