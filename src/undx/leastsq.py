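"""Weighted least-squares reconstruction of onset and detection rates.

Given two cross-sectional waves at t1 < t2 and mortality at a reference
time t' in between, candidate rates lambda0, lambda1 (parameterised
piecewise-linearly over knot ages) predict both waves by a first-order
shift along characteristics:

    p_k(t2, a) ~= p_k(t', a - h2) + h2 * RHS_k(t', a - h2 | rates)
    p_k(t1, a) ~= p_k(t', a + h1) - h1 * RHS_k(t', a + h1 | rates)

with h1 = t' - t1, h2 = t2 - t', RHS_k the transport-equation right-hand
sides, and p_k(t', .) estimated by the characteristic midpoint average of
the two waves.  The estimate minimises the standardised squared error

    X^2 = sum over waves, states, ages of (observed - predicted)^2 / sigma^2

subject to rates >= 0.  For analyses where the mortality of the
undiagnosed is itself unknown (the survey case), X^2 can be augmented by a
mortality-risk term || p_m(a) - R * pi(a) ||^2 / sigma_m^2 with the
proportionality factor R >= 0 estimated jointly and mu1 = R * mu.

The residuals are affine in the parameters, so an exact Jacobian is
supplied to a bound-constrained trust-region least-squares solver;
multi-start reduces any residual local-minimum risk.  Uncertainty is
propagated by probabilistic sensitivity analysis (:func:`run_psa`):
repeated sampling of every uncertain input followed by refitting.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats

from .core import ConfigurationError, DomainError
from .direct import (CrossSection, IncidenceEstimate, direct_inverse,
                     midpoint_prevalence)
from .forward import pde_rhs

ZERO_RATE_FLOOR = 1e-12
"""Fitted rates at or below this are treated as boundary zeros in log-scale
summaries (the optimiser parks inactive rates at tiny positive values)."""

__all__ = [
    "UncertainValues", "MortalityRiskTerm", "LSProblem", "PSAResult",
    "LogDRSummary", "midpoint_prevalence", "predict_cross_sections",
    "objective_x2", "fit_rates", "run_psa", "log_dr_uncertainty",
]


@dataclasses.dataclass
class UncertainValues:
    """Age-tabulated values with optional standard errors.

    Interpolates linearly between ages (constant beyond the ends) and can
    draw a truncated-normal (at zero) sample of itself for sensitivity
    analysis.
    """

    ages: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ConfigurationError("ages and values must be 1-d and aligned")
        if np.any(np.diff(self.ages) <= 0):
            raise ConfigurationError("ages must be strictly increasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.ages.shape or np.any(self.se < 0):
                raise ConfigurationError("se must align with ages and be >= 0")

    def at(self, ages):
        return np.interp(np.asarray(ages, dtype=float), self.ages, self.values)

    def sample(self, rng) -> "UncertainValues":
        if self.se is None:
            return self
        drawn = _truncnorm(rng, self.values, self.se, 0.0, np.inf)
        return UncertainValues(ages=self.ages, values=drawn, se=self.se)


@dataclasses.dataclass
class MortalityRiskTerm:
    """Observed mortality risk of the undiagnosed with a proportional model.

    ``pm(a)`` is the observed follow-up death risk with standard deviation
    ``sigma_m(a)``; the model risk is R * pi(a) with pi the general-
    population risk and R >= 0 the proportionality factor.  When attached
    to a problem whose ``mu1`` is unspecified, the undiagnosed mortality
    rate is taken as mu1 = R * mu with the jointly estimated R.
    """

    ages: np.ndarray
    pm: np.ndarray
    sigma_m: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        for name in ("pm", "sigma_m", "pi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.ages.shape:
                raise ConfigurationError(f"{name} must align with ages")
            setattr(self, name, arr)
        if np.any(self.sigma_m <= 0):
            raise ConfigurationError("sigma_m must be positive everywhere")
        if np.any(self.pi <= 0):
            raise ConfigurationError("pi must be positive everywhere")

    def sample(self, rng) -> "MortalityRiskTerm":
        pm = _truncnorm(rng, self.pm, self.sigma_m, 0.0, 1.0)
        return dataclasses.replace(self, pm=pm)


def _truncnorm(rng, mean, sd, lo, hi):
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.array(np.broadcast_to(mean, np.broadcast_shapes(mean.shape, sd.shape)),
                   dtype=float)
    sd = np.broadcast_to(sd, out.shape)
    pos = sd > 0
    if np.any(pos):
        a = (lo - out[pos]) / sd[pos]
        b = (hi - out[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(a, b, loc=out[pos], scale=sd[pos],
                                       random_state=rng)
    return out


@dataclasses.dataclass
class LSProblem:
    """A two-wave inverse problem posed for weighted least squares.

    Parameters
    ----------
    cs1, cs2 : CrossSection
        Survey waves at t1 < t2.
    mu, mu2 : callable, scalar, vector or UncertainValues
        General and diagnosed mortality rates (per person-year) at t'.
    mu1 : like mu, or None
        Undiagnosed mortality.  If None, a :class:`MortalityRiskTerm` must
        be supplied and mu1 = R * mu with R estimated.
    t_prime : float, optional
        Reference time, default midpoint of the waves.
    knots : array, optional
        Ages at which the rates are parameterised (piecewise linear in
        between, constant outside).  Default: one knot per evaluable age.
    eval_ages : array, optional
        Reference-time ages contributing residuals.  Default: every wave-1
        age shifted to t' whose characteristic stays inside both waves.
    sigma_mode : {"auto", "se", "unit"}
        Residual weights: survey standard errors, or sigma = 1 (the
        noise-free simulation convention).  "auto" uses standard errors
        when both waves carry them.
    mortality_risk : MortalityRiskTerm, optional
        Augments X^2 with the proportional-mortality term.
    """

    cs1: CrossSection
    cs2: CrossSection
    mu: object
    mu2: object
    mu1: object = None
    t_prime: float | None = None
    knots: np.ndarray | None = None
    eval_ages: np.ndarray | None = None
    sigma_mode: str = "auto"
    mortality_risk: MortalityRiskTerm | None = None
    eps: float = 1e-6

    def __post_init__(self):
        if self.t_prime is None:
            self.t_prime = 0.5 * (self.cs1.t + self.cs2.t)
        self.h1 = self.t_prime - self.cs1.t
        self.h2 = self.cs2.t - self.t_prime
        if self.h1 <= 0 or self.h2 <= 0:
            raise ConfigurationError("need t1 < t' < t2")
        if self.eval_ages is None:
            from .direct import default_ages
            cand = default_ages(self.cs1, self.cs2, self.t_prime)
            keep = (cand - self.h1 >= self.cs1.ages[0] - 1e-9)
            self.eval_ages = cand[keep]
        else:
            self.eval_ages = np.asarray(self.eval_ages, dtype=float)
        if self.eval_ages.size == 0:
            raise ConfigurationError("no evaluable ages inside both waves")
        if self.knots is None:
            self.knots = self.eval_ages.copy()
        else:
            self.knots = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise ConfigurationError("knots must be strictly increasing")
        if self.sigma_mode not in ("auto", "se", "unit"):
            raise ConfigurationError("sigma_mode must be auto, se or unit")
        if self.mu1 is None and self.mortality_risk is None:
            raise ConfigurationError(
                "either mu1 or a mortality_risk term must be given")

    @property
    def estimates_r(self) -> bool:
        return self.mu1 is None and self.mortality_risk is not None

    @property
    def n_params(self) -> int:
        return 2 * len(self.knots) + (1 if self.estimates_r else 0)

    def sample(self, rng) -> "LSProblem":
        """Draw one probabilistic-sensitivity replicate of all uncertain inputs."""
        return dataclasses.replace(
            self,
            cs1=_sample_cross_section(self.cs1, rng),
            cs2=_sample_cross_section(self.cs2, rng),
            mu=self.mu.sample(rng) if isinstance(self.mu, UncertainValues) else self.mu,
            mu1=self.mu1.sample(rng) if isinstance(self.mu1, UncertainValues) else self.mu1,
            mu2=self.mu2.sample(rng) if isinstance(self.mu2, UncertainValues) else self.mu2,
            mortality_risk=(self.mortality_risk.sample(rng)
                            if self.mortality_risk is not None else None),
            t_prime=self.t_prime, knots=self.knots, eval_ages=self.eval_ages)


def _sample_cross_section(cs: CrossSection, rng) -> CrossSection:
    """Truncated-normal draw of a wave's prevalences on [0, 1].

    Pairs breaching p1 + p2 <= 1 after independent truncated draws are
    rescaled to sum to just below one (rare for realistic prevalences).
    """
    if cs.se1 is None and cs.se2 is None:
        return cs
    p1 = _truncnorm(rng, cs.p1, cs.se1 if cs.se1 is not None else 0.0, 0.0, 1.0)
    p2 = _truncnorm(rng, cs.p2, cs.se2 if cs.se2 is not None else 0.0, 0.0, 1.0)
    total = p1 + p2
    bad = total > 1.0
    if np.any(bad):
        scale = (1.0 - 1e-9) / total[bad]
        p1[bad] *= scale
        p2[bad] *= scale
    return CrossSection(t=cs.t, ages=cs.ages, p1=p1, p2=p2,
                        se1=cs.se1, se2=cs.se2, n=cs.n)


def _interp_weights(x, knots):
    """Matrix W with (W @ theta)[i] = piecewise-linear interp of theta at x[i]."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    nk = len(knots)
    W = np.zeros((len(x), nk))
    if nk == 1:
        W[:, 0] = 1.0
        return W
    idx = np.clip(np.searchsorted(knots, x), 1, nk - 1)
    x0 = knots[idx - 1]
    x1 = knots[idx]
    w = np.clip((x - x0) / (x1 - x0), 0.0, 1.0)  # constant extrapolation
    W[np.arange(len(x)), idx] = w
    W[np.arange(len(x)), idx - 1] += 1.0 - w
    return W


def _mortality_values(m, problem, ages, name):
    if isinstance(m, UncertainValues):
        return m.at(ages)
    if callable(m):
        return np.asarray(m(np.full(ages.shape, problem.t_prime), ages), float)
    arr = np.asarray(m, dtype=float)
    if arr.ndim == 0:
        return np.full(ages.shape, float(arr))
    if arr.shape == ages.shape:
        return arr
    raise ConfigurationError(f"{name}: cannot align mortality input with ages")


class _Workspace:
    """Precomputed observations, weights and mortality for one problem."""

    def __init__(self, problem: LSProblem):
        p = problem
        self.problem = p
        alpha = p.eval_ages
        self.alpha = alpha
        self.W = _interp_weights(alpha, p.knots)
        self.phat1, self.phat2 = midpoint_prevalence(p.cs1, p.cs2, p.t_prime, alpha)
        a1 = alpha - p.h1
        a2 = alpha + p.h2
        self.obs = {
            ("w1", 1): p.cs1.p1_at(a1), ("w1", 2): p.cs1.p2_at(a1),
            ("w2", 1): p.cs2.p1_at(a2), ("w2", 2): p.cs2.p2_at(a2),
        }
        use_se = (p.sigma_mode == "se"
                  or (p.sigma_mode == "auto"
                      and p.cs1.se1 is not None and p.cs1.se2 is not None
                      and p.cs2.se1 is not None and p.cs2.se2 is not None))
        if p.sigma_mode == "se" and (p.cs1.se1 is None or p.cs2.se1 is None
                                     or p.cs1.se2 is None or p.cs2.se2 is None):
            raise ConfigurationError("sigma_mode='se' but waves lack standard errors")
        if use_se:
            self.sigma = {
                ("w1", 1): p.cs1.se1_at(a1), ("w1", 2): p.cs1.se2_at(a1),
                ("w2", 1): p.cs2.se1_at(a2), ("w2", 2): p.cs2.se2_at(a2),
            }
            for key, s in self.sigma.items():
                if np.any(s <= 0):
                    raise ConfigurationError(
                        f"zero standard error at a used point ({key}); "
                        "pool ages or use sigma_mode='unit'")
        else:
            ones = np.ones_like(alpha)
            self.sigma = {k: ones for k in self.obs}

        self.mu = _mortality_values(p.mu, p, alpha, "mu")
        self.mu2 = _mortality_values(p.mu2, p, alpha, "mu2")
        self.mu1 = (None if p.estimates_r
                    else _mortality_values(p.mu1, p, alpha, "mu1"))
        self.risk = p.mortality_risk

    def split(self, params):
        nk = len(self.problem.knots)
        th0 = params[:nk]
        th1 = params[nk:2 * nk]
        r = params[2 * nk] if self.problem.estimates_r else None
        return th0, th1, r

    def predictions(self, params):
        th0, th1, r = self.split(params)
        lam0 = self.W @ th0
        lam1 = self.W @ th1
        mu1 = r * self.mu if self.mu1 is None else self.mu1
        rhs1, rhs2 = pde_rhs(lam0, lam1, self.mu, mu1, self.mu2,
                             self.phat1, self.phat2)
        h1, h2 = self.problem.h1, self.problem.h2
        return {
            ("w1", 1): self.phat1 - h1 * rhs1, ("w1", 2): self.phat2 - h1 * rhs2,
            ("w2", 1): self.phat1 + h2 * rhs1, ("w2", 2): self.phat2 + h2 * rhs2,
        }

    _KEYS = (("w1", 1), ("w2", 1), ("w1", 2), ("w2", 2))

    def residuals(self, params):
        pred = self.predictions(params)
        parts = [(self.obs[k] - pred[k]) / self.sigma[k] for k in self._KEYS]
        if self.risk is not None:
            _, _, r = self.split(params)
            parts.append((self.risk.pm - r * self.risk.pi) / self.risk.sigma_m)
        return np.concatenate(parts)

    def jacobian(self, params):
        # residual r = (obs - pred)/sigma; pred_w1 = phat - h1*rhs,
        # pred_w2 = phat + h2*rhs  =>  dr_w1 = +h1 * drhs / sigma,
        # dr_w2 = -h2 * drhs / sigma.  rhs is affine in (lam0, lam1, R).
        p = self.problem
        n = len(self.alpha)
        nk = len(p.knots)
        m = 4 * n + (len(self.risk.ages) if self.risk is not None else 0)
        J = np.zeros((m, p.n_params))
        d_rhs1_l0 = 1.0 - self.phat1 - self.phat2
        d_rhs1_l1 = -self.phat1
        d_rhs2_l1 = self.phat1
        d_rhs1_r = -self.mu * self.phat1 if p.estimates_r else None

        signs = {(0, "w1"): p.h1, (1, "w2"): -p.h2, (2, "w1"): p.h1,
                 (3, "w2"): -p.h2}
        rows = [(0, ("w1", 1)), (1, ("w2", 1)), (2, ("w1", 2)), (3, ("w2", 2))]
        for block, key in rows:
            sgn = signs[(block, key[0])]
            sig = self.sigma[key]
            sl = slice(block * n, (block + 1) * n)
            if key[1] == 1:
                J[sl, :nk] = (sgn * d_rhs1_l0 / sig)[:, None] * self.W
                J[sl, nk:2 * nk] = (sgn * d_rhs1_l1 / sig)[:, None] * self.W
                if p.estimates_r:
                    J[sl, 2 * nk] = sgn * d_rhs1_r / sig
            else:
                J[sl, nk:2 * nk] = (sgn * d_rhs2_l1 / sig)[:, None] * self.W
        if self.risk is not None:
            J[4 * n:, 2 * nk] = -self.risk.pi / self.risk.sigma_m
        return J


def predict_cross_sections(problem: LSProblem, lambda0, lambda1, R=None):
    """Predicted wave prevalences for candidate rates at the knots.

    Returns a dict keyed by ``(wave, state)`` with the model values at the
    observation ages (wave 1 at ``eval_ages - h1``, wave 2 at
    ``eval_ages + h2``).
    """
    lambda0 = np.asarray(lambda0, dtype=float)
    lambda1 = np.asarray(lambda1, dtype=float)
    if np.any(lambda0 < 0) or np.any(lambda1 < 0):
        raise DomainError("candidate rates must be nonnegative")
    params = _pack(problem, lambda0, lambda1, R)
    ws = _Workspace(problem)
    pred = ws.predictions(params)
    pred["ages_w1"] = ws.alpha - problem.h1
    pred["ages_w2"] = ws.alpha + problem.h2
    return pred


def _pack(problem, lambda0, lambda1, R):
    if len(lambda0) != len(problem.knots) or len(lambda1) != len(problem.knots):
        raise ConfigurationError("rate guesses must have one value per knot")
    parts = [lambda0, lambda1]
    if problem.estimates_r:
        if R is None:
            raise ConfigurationError("problem estimates R; supply a value")
        parts.append([float(R)])
    return np.concatenate(parts)


def objective_x2(problem: LSProblem, lambda0, lambda1, R=None) -> float:
    """Standardised squared error X^2 of a candidate rate guess."""
    ws = _Workspace(problem)
    r = ws.residuals(_pack(problem, np.asarray(lambda0, float),
                           np.asarray(lambda1, float), R))
    if not np.all(np.isfinite(r)):
        raise DomainError("objective is not finite; check inputs")
    return float(np.dot(r, r))


def _starting_points(problem: LSProblem, ws: _Workspace):
    nk = len(problem.knots)
    r0 = 1.0
    if problem.estimates_r:
        r0 = float(np.clip(np.mean(ws.risk.pm) / np.mean(ws.risk.pi), 0.0, None))
    starts = []
    try:
        mu_k = _mortality_values(problem.mu, problem, problem.knots, "mu")
        mu2_k = _mortality_values(problem.mu2, problem, problem.knots, "mu2")
        mu1_k = (r0 * mu_k if problem.estimates_r
                 else _mortality_values(problem.mu1, problem, problem.knots, "mu1"))
        est = direct_inverse(problem.cs1, problem.cs2, mu=mu_k, mu1=mu1_k,
                             mu2=mu2_k, t_prime=problem.t_prime,
                             ages=problem.knots)
        lam0 = np.nan_to_num(np.clip(est.lambda0, 0.0, None), nan=0.01)
        lam1 = np.nan_to_num(np.clip(est.lambda1, 0.0, None), nan=0.01)
        starts.append(np.concatenate(
            [lam0, lam1, [r0]] if problem.estimates_r else [lam0, lam1]))
    except Exception:
        pass
    for flat in (0.01, 0.1):
        theta = np.full(2 * nk, flat)
        starts.append(np.concatenate([theta, [r0]])
                      if problem.estimates_r else theta)
    return starts


def fit_rates(problem: LSProblem, initial_guess=None,
              options: dict | None = None) -> IncidenceEstimate:
    """Bound-constrained weighted least-squares fit of (lambda0, lambda1).

    Minimises X^2 over nonnegative rates at the knot ages (and the
    mortality proportionality factor R when applicable) with a
    trust-region-reflective solver fed the exact Jacobian.  Multiple
    starting points (a direct-inverse solution plus flat low/moderate
    rates) guard against poor local minima; the best converged iterate is
    returned, flagged if no start converged.
    """
    options = dict(options or {})
    ws = _Workspace(problem)
    nk = len(problem.knots)
    if initial_guess is not None:
        starts = [np.asarray(initial_guess, dtype=float)]
        if starts[0].shape != (problem.n_params,):
            raise ConfigurationError(
                f"initial_guess must have {problem.n_params} entries")
    else:
        starts = _starting_points(problem, ws)

    lower = np.zeros(problem.n_params)
    upper = np.full(problem.n_params, np.inf)
    best = None
    tried = 0
    for x0 in starts:
        x0 = np.clip(x0, lower, None)
        try:
            res = optimize.least_squares(
                ws.residuals, x0, jac=ws.jacobian, bounds=(lower, upper),
                method="trf",
                xtol=options.get("xtol", 1e-14),
                ftol=options.get("ftol", 1e-14),
                gtol=options.get("gtol", 1e-14),
                max_nfev=options.get("max_nfev", 2000))
        except Exception:
            continue
        tried += 1
        if not np.isfinite(res.cost):
            raise DomainError("objective became NaN during optimisation")
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise DomainError("every optimisation start failed")

    th0, th1, r = ws.split(best.x)
    return IncidenceEstimate(
        t_prime=float(problem.t_prime), ages=problem.knots.copy(),
        lambda0=th0.copy(), lambda1=th1.copy(),
        flags=np.zeros(nk, dtype=int),
        meta={"method": "least_squares", "X2": 2.0 * float(best.cost),
              "converged": bool(best.status > 0), "n_iter": int(best.nfev),
              "n_starts": tried, "R": None if r is None else float(r)})


@dataclasses.dataclass
class PSAResult:
    """Monte-Carlo draws of the least-squares estimates.

    ``lambda0_draws``/``lambda1_draws`` have shape (n_draws, n_knots) with
    NaN rows for failed fits; summaries are always recomputed from the
    stored draws.
    """

    ages: np.ndarray
    lambda0_draws: np.ndarray
    lambda1_draws: np.ndarray
    r_draws: np.ndarray | None
    ok: np.ndarray
    seed: int
    base: IncidenceEstimate

    @property
    def n_draws(self) -> int:
        return self.lambda0_draws.shape[0]

    @property
    def failure_fraction(self) -> float:
        return 1.0 - float(np.mean(self.ok))

    def _ok_draws(self, arr):
        return arr[self.ok]

    @property
    def mean_lambda0(self):
        return np.mean(self._ok_draws(self.lambda0_draws), axis=0)

    @property
    def mean_lambda1(self):
        return np.mean(self._ok_draws(self.lambda1_draws), axis=0)

    @property
    def sd_lambda0(self):
        return np.std(self._ok_draws(self.lambda0_draws), axis=0, ddof=1) \
            if self.ok.sum() > 1 else np.zeros(len(self.ages))

    @property
    def sd_lambda1(self):
        return np.std(self._ok_draws(self.lambda1_draws), axis=0, ddof=1) \
            if self.ok.sum() > 1 else np.zeros(len(self.ages))

    def log_cov(self):
        """Per-age covariance matrix of (log lambda0, log lambda1).

        Draws with a nonpositive rate at an age are excluded at that age.
        Returns (cov array of shape (n_ages, 2, 2), n_used, n_excluded).
        """
        n_ages = len(self.ages)
        cov = np.full((n_ages, 2, 2), np.nan)
        used = np.zeros(n_ages, dtype=int)
        l0 = self._ok_draws(self.lambda0_draws)
        l1 = self._ok_draws(self.lambda1_draws)
        for j in range(n_ages):
            good = (l0[:, j] > ZERO_RATE_FLOOR) & (l1[:, j] > ZERO_RATE_FLOOR)
            used[j] = int(good.sum())
            if used[j] > 1:
                cov[j] = np.cov(np.log(l0[good, j]), np.log(l1[good, j]),
                                ddof=1)
        excluded = l0.shape[0] - used
        return cov, used, excluded

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "a": self.ages,
            "lambda0": self.base.lambda0, "sd_lambda0": self.sd_lambda0,
            "lambda1": self.base.lambda1, "sd_lambda1": self.sd_lambda1,
        })


def run_psa(problem: LSProblem, n_draws: int, seed: int,
            keep_failures: bool = True) -> PSAResult:
    """Probabilistic sensitivity analysis by input resampling and refitting.

    A single integer seed governs the whole analysis; per-draw random
    substreams are spawned deterministically, so results are reproducible
    and independent of execution order.  Failed fits are recorded and
    excluded from summaries.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    base = fit_rates(problem)
    base_params = _pack(problem, base.lambda0, base.lambda1, base.meta["R"])
    nk = len(problem.knots)
    l0 = np.full((n_draws, nk), np.nan)
    l1 = np.full((n_draws, nk), np.nan)
    rr = np.full(n_draws, np.nan) if problem.estimates_r else None
    ok = np.zeros(n_draws, dtype=bool)

    streams = np.random.SeedSequence(seed).spawn(n_draws)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            drawn = problem.sample(rng)
            est = fit_rates(drawn, initial_guess=base_params)
        except Exception:
            continue
        l0[i] = est.lambda0
        l1[i] = est.lambda1
        if rr is not None:
            rr[i] = est.meta["R"]
        ok[i] = True
    if not ok.any():
        raise DomainError("every sensitivity draw failed to fit")
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} of {n_draws} sensitivity draws failed "
                      "and were excluded", RuntimeWarning, stacklevel=2)
    return PSAResult(ages=problem.knots.copy(), lambda0_draws=l0,
                     lambda1_draws=l1, r_draws=rr, ok=ok, seed=int(seed),
                     base=base)


@dataclasses.dataclass(frozen=True)
class LogDRSummary:
    """Per-age mean and SD of the log detection ratio from PSA draws."""

    ages: np.ndarray
    mean_log_dr: np.ndarray
    sd_log_dr: np.ndarray          # via Var(log l1) + Var(log l0) - 2 Cov
    sd_log_dr_empirical: np.ndarray  # direct SD of per-draw differences
    n_used: np.ndarray
    n_excluded: np.ndarray


def log_dr_uncertainty(psa: PSAResult) -> LogDRSummary:
    """Log-scale detection-ratio uncertainty from stored PSA draws.

    log DR = log lambda1 - log lambda0, so Var(log DR) =
    Var(log lambda1) + Var(log lambda0) - 2 Cov(log lambda0, log lambda1).
    The variance-formula SD is cross-checked against the empirical SD of
    the per-draw log differences (they are algebraically identical on the
    same draws).  Draws with a nonpositive rate are excluded per age.
    """
    cov, used, excluded = psa.log_cov()
    n_ages = len(psa.ages)
    mean = np.full(n_ages, np.nan)
    sd_formula = np.full(n_ages, np.nan)
    sd_emp = np.full(n_ages, np.nan)
    l0 = psa.lambda0_draws[psa.ok]
    l1 = psa.lambda1_draws[psa.ok]
    for j in range(n_ages):
        good = (l0[:, j] > ZERO_RATE_FLOOR) & (l1[:, j] > ZERO_RATE_FLOOR)
        if good.sum() < 2:
            continue
        diff = np.log(l1[good, j]) - np.log(l0[good, j])
        mean[j] = diff.mean()
        sd_emp[j] = diff.std(ddof=1)
        sd_formula[j] = np.sqrt(max(cov[j, 1, 1] + cov[j, 0, 0]
                                    - 2 * cov[j, 0, 1], 0.0))
    if np.any(excluded > 0):
        warnings.warn("draws with nonpositive rates were excluded from the "
                      "log-DR summary", RuntimeWarning, stacklevel=2)
    return LogDRSummary(ages=psa.ages.copy(), mean_log_dr=mean,
                        sd_log_dr=sd_formula, sd_log_dr_empirical=sd_emp,
                        n_used=used, n_excluded=excluded)
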