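# Methods

## Model and assumptions

`undx` implements a four-state compartment model for irreversible chronic
disease: *Normal* → *Undiagnosed* → *Diagnosed*, with death from every
living state.  The state occupancies depend on calendar time `t` (years
since an epoch; the bundled scenario uses 1900) and age `a`.  Assumptions:

* the disease is irreversible (no remission back to *Normal*);
* no transition rate depends on disease duration, only on `(t, a)`;
* the population is closed apart from births (no migration);
* prevalences vanish at age 0 — the disease is contracted after birth.

In prevalence form the dynamics reduce to two coupled transport equations
(see README) that involve the overall mortality `μ` rather than the
unobservable mortality of the healthy `μ0`; `μ0` appears only in the
absolute-count formulation and in the consistency identity
`μ = p0 μ0 + p1 μ1 + p2 μ2`, which the package exposes as
`overall_mortality` / `infer_mu0`.  Pooling the two disease states
reproduces the classical illness-death equation
`(∂t+∂a)p = (1−p)[λ0 − (μ−μ0)]`, which serves as a solver diagnostic
(`check_illness_death_consistency`; its forward-difference residual decays
first order in the grid step, and the test suite verifies that decay).

## Numerical scheme

Along a characteristic `t − a = const` the PDE system is an ODE in age.
Every requested node is integrated independently from age 0 of its own
birth cohort with classical fourth-order Runge–Kutta, default step 0.25
years (`forward.DEFAULT_STEP`).  Per-cohort steps divide the target age
exactly, so integer-aligned rate discontinuities (such as the scenario's
discovery year) fall on step boundaries and the scheme retains its order;
the suite checks ~16× error reduction per step halving.  Values may leave
[0, 1] by at most 1e-9 (clipped); larger excursions raise an instability
error rather than being hidden.  Rate surfaces are evaluated through their
own callable contract at every stage — nothing is pre-tabulated — so
closed-form rates are honoured exactly.

## Inverse routes

**Closed-form ("direct") route.**  The characteristic derivative at the
reference time `t′` is the two-wave difference
`[p_k(t₂, a+t₂−t′) − p_k(t₁, a−t′+t₁)]/(t₂−t₁)` with linear interpolation
between tabulated survey ages; `t′` defaults to the wave midpoint.  The
rate formulas then need `p_k(t′, a)` itself: in simulation experiments the
exact forward solution can be supplied (`p_tprime=`), which isolates the
finite-difference error; otherwise the characteristic midpoint average
`h₂/(h₁+h₂)·p_k(t₁, a−h₁) + h₁/(h₁+h₂)·p_k(t₂, a+h₂)` is used.  Negative
raw estimates (possible with noisy data) are reported as-is with a flag;
`IncidenceEstimate.sanitized()` gives the clamped view.  Division guards
default to 1e-6 on `p1` and `1−p1−p2`; failing ages are flagged-undefined,
not raised, so batch inversion proceeds.

**Least-squares route.**  Candidate rates are piecewise linear in age over
knots (constant beyond the end knots).  Both waves are predicted from the
midpoint estimate of `p_k(t′, ·)` by a first-order shift along the
characteristic, with the transport right-hand sides evaluated at the
candidate rates.  One wave-prediction formula in the source experiment is
stated with the age shifted by `−h₁` where the characteristic geometry
(and the midpoint estimator printed beside it) requires `+h₁`; this
package uses the characteristic-consistent form, predicting the wave-1
observation at age `a` from the reference point at age `a + h₁`.  The
objective is the standardised squared error over both waves and states
(survey standard errors, or σ = 1 for noise-free experiments), optionally
augmented by `‖p_m(a) − R·π(a)‖²/σ_m²` with `R ≥ 0` appended to the
parameter vector and `μ1 = R·μ`.  Because the residuals are affine in the
parameters, the exact Jacobian is supplied to SciPy's bound-constrained
trust-region-reflective least-squares solver (tolerances 1e-14); three
starting points (a direct-inverse solution, flat 0.01/py, flat 0.1/py)
guard against boundary-induced local minima, and the best converged
iterate wins.  With equal weights and symmetric waves the minimiser
coincides with the closed-form solution evaluated at the midpoint
prevalences — the suite asserts this identity, which also explains why the
least-squares route is the (slightly) less accurate one on noise-free
data: it must estimate `p(t′, ·)` from the waves.

## Detection ratio

`DR = λ1/λ0` is a hazard ratio (undefined where `λ0 ≤ 0`).  The threshold
`Δ = p0/p1 + (μ−μ1)/λ0` classifies the trend of the undiagnosed
prevalence along the aging direction: DR < Δ → increasing, DR > Δ →
decreasing, equality (relative tolerance 1e-8, since exact equality is
measure-zero) → stationary.  Undefined inputs propagate to an "undefined"
verdict.  The sign law is instantaneous; the test suite verifies it at
1,000 random scenario nodes with a finite-difference proxy, excluding
steps that cross the discovery-year rate discontinuity and a 5 % band
around stationarity.

## Probabilistic sensitivity analysis

Every uncertain input — wave prevalences, tabulated mortality rates, the
observed mortality risk of the undiagnosed — is resampled and the model
refitted.  Sampling distributions are truncated normal: on [0, 1] for
proportions and risks, at 0 for rates (the sampling family is a
configuration choice, not an identified quantity; truncation keeps every
draw in its physical domain).  Prevalence pairs breaching `p1 + p2 ≤ 1`
after independent draws are rescaled to sum just below one; at realistic
prevalences this is vanishingly rare.  One integer seed governs the whole
analysis through deterministically spawned per-draw substreams, so results
are bitwise reproducible and order-independent.  Per-draw fits start from
the base estimate; failures are recorded, warned about and excluded from
summaries.  `log DR = log λ1 − log λ0` is summarised per age with the
variance formula `Var(log λ1) + Var(log λ0) − 2 Cov`, cross-checked
against the empirical SD of per-draw differences (an algebraic identity on
the same draws, asserted to 1e-12); draws with a rate at the zero bound
(≤ 1e-12) are excluded from log-scale summaries with a warning.

## Bundled scenario

The hypothetical-disease scenario is fully closed-form:

* general mortality `μ(t,a) = exp(β0(t) + β1(t)·a)` with
  `β0 = −7.078 − 0.02592 t`, `β1 = 0.06401 + 2.455e-4 t` (a Gompertz-type
  approximation to 20th-century German male mortality);
* `μ1 = 3.5 μ`, `μ2 = 2.5 μ` (untreated disease carries the larger excess;
  dementia-like magnitudes);
* `λ0` from an age table (0 at and below age 62.5, rising to 16.8 per 100
  person-years at and above 100), `λ1` zero before the discovery year 75,
  then an age profile with a nearly age-constant ratio `λ1/λ0 ≈ 7.4`
  growing 1 % per year.

Two conventions are not pinned down by the experiment's description and
are therefore explicit toggles with documented defaults: the age tables
are read as 5-year band midpoints 62.5…97.5 with **linear interpolation**
between them (constant outside), and the 1 %/yr growth is **compound**
(`1.01^(t−75)`; a linear variant is available).  These conventions are the
dominant source of spread in the reconstruction-error statistics: the
finite-difference error of the inverse routes concentrates at the table's
slope breaks (ages ≈ 72.5 and 100), so the *maximum* relative errors —
unlike the medians and the λ0 maxima — can shift by several tenths of a
percentage point under a different interpolation rule.  The acceptance
script reports the values produced by the stated defaults.

## Synthetic survey generator

`scenario.hrs_like_study` emulates a biannual survey of ages 50–95 with a
two-year mortality follow-up, for exercising the full survey workflow
without any external data:

* truth: a diabetes-like disease — onset ramping 0 → 1.2/100 py by age 54
  and linearly to 2.0/100 py at 86 (exactly representable by the default
  8-year knots 54…86, so recovery tests measure sampling error, not
  parameterisation bias), flat detection 25/100 py, `μ1 = 2 μ`,
  `μ2 = 1.5 μ`;
* waves at t = 106 and 108 sampled multinomially per age (default 400 per
  age; recovery tests use 10⁶ so the estimator is in its Gaussian regime);
* follow-up cohorts of 400 (general), 80 (diagnosed) and 6 (undiagnosed)
  per age — the deliberately tiny undiagnosed cohort mirrors the dominant
  uncertainty of real survey analyses of undiagnosed disease;
* deaths drawn binomially from the window risk
  `1 − exp(−∫ μ_state ds)` along the aging path (Simpson quadrature);
* general and diagnosed risks smoothed by a binomial GLM (logit link) in
  age and averaged over two-year bins; risks are converted to rates by
  `−log(1−risk)/w` and attributed to the **midpoint age** `a + w/2` of the
  window (attributing to `a` would overstate an age-increasing hazard by
  about the hazard's growth over half the window, ~9 % here);
* the undiagnosed mortality enters only through the proportional-risk
  term, with `R` estimated jointly;
* boundary-count standard errors use a continuity correction
  `(x+0.5)/(n+1)` so weights stay positive when a cell is empty.

What the generator does **not** emulate: survey design weights and
clustering, item nonresponse, measurement error in the biomarker defining
"undiagnosed", age heaping, migration, and duration-dependent rates.
Passing recovery tests therefore demonstrate that the estimators invert
their own data-generating model under realistic sampling noise — not that
the model is correctly specified for any particular real survey.

## Problem sizes and tolerances

Default experiment sizes keep the whole suite in the tens of seconds: the
inversion experiments use 31 reference ages (70–100) from waves tabulated
at integer ages 55–106; forward landmarks use a 0.25-year age grid;
sensitivity analyses use 500 draws for the survey workflow (the package
default for the `psa` subcommand) and fewer for scaling checks.  Closure
is enforced to 1e-9 on exact surfaces (looser, binomial-derived tolerances
apply to sampled surveys); division guards default to 1e-6; unit
conversions are lossless to one unit in the last place.

## Known limitations

* Irreversibility is structural: diseases with non-negligible remission
  (e.g. diabetes after bariatric surgery) violate the model at the margin.
* The inverse routes are first-order in the wave separation; widely
  spaced waves bias the estimates beyond what the sensitivity analysis
  reports.
* The direct route applies no smoothing; with noisy input it should be
  used diagnostically and the least-squares route for estimation.
* The proportional-mortality model for the undiagnosed (`μ1 = R μ` with a
  single global R) is an approximation; the true risk ratio of a
  proportional-hazards pair drifts with age over a finite window.
* Sensitivity analysis conditions on the observed data; it propagates
  input uncertainty but not model misspecification.
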