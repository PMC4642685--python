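"""Bundled simulation scenario and synthetic survey generators.

The hypothetical-disease scenario describes an irreversible chronic disease
that is unknown to medicine until the discovery year t* = 75 (t counted in
years since 1900).  Its ingredients:

* General mortality follows a Gompertz-type surface
  mu(t, a) = exp(beta0(t) + beta1(t) * a) with
  beta0(t) = -7.078 - 0.02592 t and beta1(t) = 0.06401 + 2.455e-4 t
  (an approximation to 20th-century German male mortality).
* Undiagnosed and diagnosed mortality are proportional to it:
  mu1 = 3.5 mu and mu2 = 2.5 mu (untreated disease carries the higher
  excess; magnitudes are dementia-like).
* The onset rate lambda0 depends on age only (1.5x a dementia incidence
  table); the detection rate lambda1 is zero before t*, jumps to an
  age profile with a nearly age-constant ratio lambda1/lambda0 ~ 7.4 at
  t*, and then grows by 1 % per year (compound by default).

Age tables are read as 5-year band midpoints 62.5 ... 97.5 (zero at and
below 62.5, constant at and above 100) with linear interpolation between
midpoints.

A second family of helpers fabricates survey-style data from any rate set:
multinomial prevalence sampling of a cross-section, binomial mortality
follow-up over a window, logistic age-smoothing of mortality risk, and a
complete synthetic biannual-survey study (diabetes-like defaults) for
exercising the survey workflow end to end.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import ConfigurationError, DomainError, RateSet, RateSurface
from .direct import CrossSection
from .forward import DEFAULT_STEP, prevalence_at
from .leastsq import LSProblem, MortalityRiskTerm, UncertainValues

DISCOVERY_TIME = 75.0
ANNUAL_GROWTH = 0.01
UNDIAGNOSED_MORTALITY_FACTOR = 3.5
DIAGNOSED_MORTALITY_FACTOR = 2.5

#: age-band midpoints of the incidence table (years)
AGE_MIDPOINTS = np.array([62.5, 67.5, 72.5, 77.5, 82.5, 87.5, 92.5, 97.5, 100.0])
#: onset rate lambda0 at the midpoints, per 100 person-years
LAMBDA0_PER100 = np.array([0.0, 0.45, 1.05, 2.55, 4.50, 7.80, 11.40, 14.85, 16.80])
#: detection rate lambda1 at the midpoints in the discovery year, per 100 py
LAMBDA1_T75_PER100 = np.array([0.0, 3.3, 7.8, 18.8, 33.3, 57.6, 84.2, 109.7, 124.1])

_BETA0 = (-7.078, -0.02592)
_BETA1 = (0.06401, 2.455e-4)


def general_mortality(t, a):
    """Gompertz-type general mortality mu(t, a), per person-year."""
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    b0 = _BETA0[0] + _BETA0[1] * t
    b1 = _BETA1[0] + _BETA1[1] * t
    return np.exp(b0 + b1 * a)


def onset_rate(a):
    """Age-specific onset rate lambda0(a), per person-year."""
    return np.interp(np.asarray(a, dtype=float), AGE_MIDPOINTS,
                     LAMBDA0_PER100) / 100.0


def detection_rate(t, a, growth: str = "compound"):
    """Detection rate lambda1(t, a), per person-year.

    Zero before the discovery year; afterwards the tabulated age profile
    grows 1 % per year, compounded by default ((1 + g)^(t - t*)) or
    linearly (1 + g (t - t*)) when ``growth='linear'``.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    base = np.interp(a, AGE_MIDPOINTS, LAMBDA1_T75_PER100) / 100.0
    dt = t - DISCOVERY_TIME
    if growth == "compound":
        factor = np.where(dt >= 0, (1.0 + ANNUAL_GROWTH) ** np.maximum(dt, 0.0), 0.0)
    elif growth == "linear":
        factor = np.where(dt >= 0, 1.0 + ANNUAL_GROWTH * np.maximum(dt, 0.0), 0.0)
    else:
        raise ConfigurationError("growth must be 'compound' or 'linear'")
    return base * factor


def build_scenario(growth: str = "compound") -> RateSet:
    """Assemble the hypothetical-disease rate set on t, a in [0, 110].

    Repeated calls return functionally identical surfaces (the builder is
    pure).  The returned set has mu1 = 3.5 mu and mu2 = 2.5 mu.
    """
    mu = RateSurface(fn=general_mortality, name="mu")
    return RateSet(
        lambda0=RateSurface(fn=lambda t, a: onset_rate(a)
                            + np.zeros(np.broadcast_shapes(np.shape(t), np.shape(a))),
                            name="lambda0"),
        lambda1=RateSurface(fn=lambda t, a, _g=growth: detection_rate(t, a, growth=_g),
                            name="lambda1"),
        mu=mu,
        mu1=mu.scaled(UNDIAGNOSED_MORTALITY_FACTOR, name="mu1"),
        mu2=mu.scaled(DIAGNOSED_MORTALITY_FACTOR, name="mu2"),
    )


# ---------------------------------------------------------------------------
# synthetic survey machinery


@dataclasses.dataclass(frozen=True)
class SyntheticSurveyConfig:
    """Design of a fabricated cross-sectional survey.

    ``wave_times`` are the calendar times of the waves, ``ages`` the
    tabulated survey ages, ``n_per_age`` the number of sampled persons per
    age (scalar or per-age vector), ``followup_years`` the mortality
    observation window, and ``seed`` the mandatory RNG seed.
    """

    wave_times: tuple
    ages: np.ndarray
    n_per_age: object
    seed: int
    followup_years: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        n = np.broadcast_to(np.asarray(self.n_per_age), self.ages.shape)
        if np.any(n < 1):
            raise ConfigurationError("sample sizes must be >= 1")
        if self.followup_years <= 0:
            raise ConfigurationError("follow-up window must be positive")


def _binomial_se(counts, n):
    """Standard error of a proportion; continuity-corrected when the count
    is at the boundary so downstream weights stay positive."""
    phat = counts / n
    shrunk = np.where((counts == 0) | (counts == n),
                      (counts + 0.5) / (n + 1.0), phat)
    return np.sqrt(shrunk * (1.0 - shrunk) / n)


def synth_cross_section(rates: RateSet, t: float, ages, n, rng,
                        step: float = DEFAULT_STEP) -> CrossSection:
    """Multinomial sample of a cross-section from the model's prevalences.

    Per age, ``n`` persons are assigned to (undiagnosed, diagnosed,
    neither) with probabilities (p1, p2, p0) from the forward solution;
    estimated proportions carry binomial standard errors.
    """
    ages = np.asarray(ages, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=int), ages.shape).copy()
    if np.any(n < 1):
        raise ConfigurationError("n must be >= 1 at every age")
    p1, p2 = prevalence_at(rates, t, ages, step=step)
    counts = np.empty((len(ages), 3))
    for i in range(len(ages)):
        counts[i] = rng.multinomial(n[i], [p1[i], p2[i], 1.0 - p1[i] - p2[i]])
    p1_hat = counts[:, 0] / n
    p2_hat = counts[:, 1] / n
    return CrossSection(t=float(t), ages=ages, p1=p1_hat, p2=p2_hat,
                        se1=_binomial_se(counts[:, 0], n),
                        se2=_binomial_se(counts[:, 1], n), n=n)


_STATE_RATE = {"general": "mu", "undiagnosed": "mu1", "diagnosed": "mu2"}


def window_death_risk(rates: RateSet, state: str, t: float, ages,
                      window: float, n_quad: int = 64):
    """Probability of dying within ``window`` years along the aging path.

    risk = 1 - exp(-integral_0^w mu_state(t + s, a + s) ds), evaluated by
    composite Simpson quadrature along the characteristic.
    """
    if state not in _STATE_RATE:
        raise ConfigurationError(f"state must be one of {sorted(_STATE_RATE)}")
    surface = getattr(rates, _STATE_RATE[state])
    ages = np.asarray(ages, dtype=float)
    s = np.linspace(0.0, window, 2 * n_quad + 1)
    vals = surface(t + s[None, :], ages[:, None] + s[None, :])
    from scipy.integrate import simpson
    integral = simpson(vals, x=s, axis=1)
    return 1.0 - np.exp(-integral)


def synth_mortality_followup(rates: RateSet, state: str, t: float, ages, n,
                             window: float, rng) -> pd.DataFrame:
    """Binomial death counts over a follow-up window for one population.

    Returns a frame with per-age deaths, n, estimated risk, its binomial
    standard error and the model's true window risk.
    """
    ages = np.asarray(ages, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=int), ages.shape).copy()
    risk = window_death_risk(rates, state, t, ages, window)
    deaths = rng.binomial(n, risk)
    return pd.DataFrame({
        "a": ages, "deaths": deaths, "n": n,
        "risk_hat": deaths / n,
        "se": _binomial_se(deaths.astype(float), n),
        "true_risk": risk,
    })


def smooth_mortality_risk(ages, deaths, n, bin_width: int = 2) -> pd.DataFrame:
    """Logistic age-smoothing of death risks, averaged over age bins.

    Fits a binomial GLM (logit link) of death on age, converts the linear
    predictor back to probabilities on a one-year age grid and averages
    within consecutive ``bin_width``-year bins (e.g. 50-51, 52-53, ...).
    Returns columns age_lo, age_hi, a (bin midpoint), risk, se.
    """
    import statsmodels.api as sm

    ages = np.asarray(ages, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    n = np.asarray(n, dtype=float)
    if deaths.sum() <= 0:
        raise DomainError("no deaths observed; pool more data before smoothing")
    if len(np.unique(ages[deaths > 0])) < 2:
        raise DomainError("events at fewer than two distinct ages; "
                          "pool adjacent ages before smoothing")
    exog = sm.add_constant(ages)
    model = sm.GLM(np.column_stack([deaths, n - deaths]), exog,
                   family=sm.families.Binomial())
    fit = model.fit()

    grid = np.arange(np.floor(ages.min()), np.floor(ages.max()) + 1)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame()
    risk = pred["mean"].to_numpy()
    se = pred["mean_se"].to_numpy()

    rows = []
    for lo in np.arange(grid[0], grid[-1] + 1, bin_width):
        sel = (grid >= lo) & (grid < lo + bin_width)
        if not sel.any():
            continue
        rows.append({"age_lo": lo, "age_hi": grid[sel].max(),
                     "a": grid[sel].mean(),
                     "risk": risk[sel].mean(), "se": se[sel].mean()})
    return pd.DataFrame(rows)


def risk_to_rate(risk, window: float):
    """Convert a window death risk to a constant hazard: -log(1-risk)/w."""
    risk = np.asarray(risk, dtype=float)
    if np.any(risk >= 1):
        raise DomainError("risk must be below 1")
    return -np.log1p(-risk) / window


# ---------------------------------------------------------------------------
# complete synthetic biannual-survey study (diabetes-like defaults)


def diabetes_like_rates() -> RateSet:
    """A diabetes-like truth for the synthetic survey study.

    Onset ramps from zero before age 40 to 1.2/100 py at 54 and linearly to
    2.0/100 py at 86 (constant beyond) — exactly representable by 8-year
    knots 54...86; detection is a flat 25/100 py; mortality is the bundled
    Gompertz surface with mu1 = 2.0 mu and mu2 = 1.5 mu.
    """
    mu = RateSurface(fn=general_mortality, name="mu")
    lam0 = RateSurface.from_age_profile(
        ages=[0.0, 40.0, 54.0, 86.0, 110.0],
        values=np.array([0.0, 0.0, 1.2, 2.0, 2.0]) / 100.0, name="lambda0")
    return RateSet(lambda0=lam0,
                   lambda1=RateSurface.constant(25.0 / 100.0, name="lambda1"),
                   mu=mu, mu1=mu.scaled(2.0, name="mu1"),
                   mu2=mu.scaled(1.5, name="mu2"))


@dataclasses.dataclass
class SyntheticStudy:
    """A fabricated two-wave survey with mortality follow-up, plus truth."""

    problem: LSProblem
    config: SyntheticSurveyConfig
    rates: RateSet
    truth_lambda0: np.ndarray
    truth_lambda1: np.ndarray
    r_true_risk_ratio: float
    followup: dict


def hrs_like_study(seed: int,
                   wave_times: tuple = (106.0, 108.0),
                   ages=None,
                   n_prevalence: int = 400,
                   n_general: int = 400,
                   n_diagnosed: int = 80,
                   n_undiagnosed: int = 6,
                   followup_years: float = 2.0,
                   knots=None,
                   rates: RateSet | None = None) -> SyntheticStudy:
    """Fabricate a biannual-survey study emulating an HRS-style design.

    Two prevalence waves two years apart (multinomial sampling at ages
    50-95), a two-year mortality follow-up for the general, diagnosed and
    undiagnosed populations (the undiagnosed cohort deliberately small, as
    in real surveys), logistic two-year-binned smoothing for the general
    and diagnosed risks, and a proportional-mortality term for the
    undiagnosed.  Returns an :class:`LSProblem` ready for
    :func:`undx.leastsq.fit_rates` / :func:`undx.leastsq.run_psa` together
    with the generating truth at the knots.
    """
    ages = np.arange(50.0, 96.0) if ages is None else np.asarray(ages, float)
    knots = np.arange(54.0, 87.0, 8.0) if knots is None \
        else np.asarray(knots, dtype=float)
    rates = diabetes_like_rates() if rates is None else rates
    config = SyntheticSurveyConfig(wave_times=tuple(wave_times), ages=ages,
                                   n_per_age=n_prevalence, seed=int(seed),
                                   followup_years=followup_years)
    rng = np.random.default_rng(seed)

    cs1 = synth_cross_section(rates, wave_times[0], ages, n_prevalence, rng)
    cs2 = synth_cross_section(rates, wave_times[1], ages, n_prevalence, rng)
    t_prime = 0.5 * (wave_times[0] + wave_times[1])

    fu = {state: synth_mortality_followup(
        rates, state, wave_times[0], ages, n, followup_years, rng)
        for state, n in (("general", n_general), ("diagnosed", n_diagnosed),
                         ("undiagnosed", n_undiagnosed))}

    gen = smooth_mortality_risk(fu["general"]["a"], fu["general"]["deaths"],
                                fu["general"]["n"])
    dia = smooth_mortality_risk(fu["diagnosed"]["a"], fu["diagnosed"]["deaths"],
                                fu["diagnosed"]["n"])
    # A window risk over [a, a + w] reflects the average hazard on that
    # stretch of the aging path, i.e. the rate near age a + w/2; attributing
    # it to age a would overstate an age-increasing mortality.
    w = followup_years
    mu_uv = UncertainValues(gen["a"].to_numpy() + w / 2,
                            risk_to_rate(gen["risk"].to_numpy(), w),
                            se=gen["se"].to_numpy()
                            / ((1.0 - gen["risk"].to_numpy()) * w))
    mu2_uv = UncertainValues(dia["a"].to_numpy() + w / 2,
                             risk_to_rate(dia["risk"].to_numpy(), w),
                             se=dia["se"].to_numpy()
                             / ((1.0 - dia["risk"].to_numpy()) * w))

    und = fu["undiagnosed"]
    pi_at_und = np.interp(und["a"].to_numpy(), gen["a"].to_numpy(),
                          gen["risk"].to_numpy())
    risk_term = MortalityRiskTerm(ages=und["a"].to_numpy(),
                                  pm=und["risk_hat"].to_numpy(),
                                  sigma_m=und["se"].to_numpy(),
                                  pi=pi_at_und)

    # residuals only at ages where the 8-year-knot parameterisation applies
    eval_ages = np.arange(knots[0], knots[-1] + 1.0)
    problem = LSProblem(cs1=cs1, cs2=cs2, mu=mu_uv, mu1=None, mu2=mu2_uv,
                        t_prime=t_prime, knots=knots, eval_ages=eval_ages,
                        sigma_mode="se", mortality_risk=risk_term)

    true_general = window_death_risk(rates, "general", wave_times[0], ages, w)
    true_und = window_death_risk(rates, "undiagnosed", wave_times[0], ages, w)
    return SyntheticStudy(
        problem=problem, config=config, rates=rates,
        truth_lambda0=rates.lambda0(np.full(knots.shape, t_prime), knots),
        truth_lambda1=rates.lambda1(np.full(knots.shape, t_prime), knots),
        r_true_risk_ratio=float(np.mean(true_und / true_general)),
        followup=fu)
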