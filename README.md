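# undx — incidence of undiagnosed chronic disease from prevalence data

Most major chronic diseases — diabetes, dementia, chronic kidney disease —
pass through a phase in which the clinical threshold has been met but no
diagnosis has been made.  Cross-sectional surveys can measure how *prevalent*
the undiagnosed and diagnosed states are, but the quantities that drive an
epidemic — the onset rate of undetected disease and the rate at which
existing cases are found — are transition *rates* that normally require
long follow-up studies.  `undx` closes that gap: it estimates both rates
from two prevalence cross-sections plus mortality data.

## The model

The living population at calendar time *t* and age *a* is split into
*Normal*, *Undiagnosed* and *Diagnosed* states, with death reachable from
each.  Writing `p1`, `p2` for the prevalences of the undiagnosed and
diagnosed states, `λ0` for the onset rate (Normal → Undiagnosed), `λ1` for
the detection rate (Undiagnosed → Diagnosed), `μ` for overall mortality and
`μ1`, `μ2` for the state-specific mortalities, the dynamics are an
age-structured transport system

    (∂t + ∂a) p1 = −(λ0 + λ1 + μ1 − μ) p1 − λ0 p2 + λ0
    (∂t + ∂a) p2 = λ1 p1 − (μ2 − μ) p2,        p1(t,0) = p2(t,0) = 0.

`undx` provides

* a **forward solver** (4th-order Runge–Kutta along characteristics) for
  prevalences, and for absolute counts given a newborn supply;
* a **closed-form inverse**: with the characteristic derivative
  approximated from two waves at t₁ < t′ < t₂,
  `λ1 = [(∂t+∂a)p2 + (μ2−μ) p2] / p1` and
  `λ0 = [(∂t+∂a)p1 + (λ1+μ1−μ) p1] / (1−p1−p2)`;
* a **weighted least-squares inverse** `λ = argmin_{λ≥0} X²(λ)`, where X²
  sums standardised squared deviations between the observed waves and
  first-order predictions from a candidate rate set — optionally augmented
  by a proportional-mortality term `‖p_m(a) − R·π(a)‖²/σ_m²` that estimates
  the unknown mortality of the undiagnosed as `μ1 = R·μ`;
* the **detection ratio** `DR = λ1/λ0` (a hazard ratio) and its growth
  threshold `Δ = p0/p1 + (μ−μ1)/λ0`: DR < Δ means the undiagnosed
  prevalence is rising along the aging direction, DR > Δ that it is
  falling;
* **probabilistic sensitivity analysis**: resample every uncertain input,
  refit, and summarise — including the variance of
  `log DR = log λ1 − log λ0` from the log-scale covariance;
* **synthetic-data generators**: a fully specified hypothetical-disease
  scenario (Gompertz mortality, tabulated age-specific incidence, disease
  discovery at year 75 with 1 %/yr growth in detection) and a biannual
  survey emulator (multinomial prevalence sampling, binomial mortality
  follow-up, logistic age-smoothing).

All rates are per person-year internally; tables per 100 person-years are
converted at the I/O boundary.

## Worked example

Reconstruct onset and detection of a diabetes-like disease from two
simulated survey waves (20 000 respondents per age, two years apart), with
uncertainty from a 200-draw sensitivity analysis:

```python
import numpy as np
from undx import scenario
from undx.model import UndiagnosedDiseaseModel

rates = scenario.diabetes_like_rates()          # generating truth
ages = np.arange(50.0, 96.0)
rng = np.random.default_rng(42)
cs1 = scenario.synth_cross_section(rates, 106.0, ages, 20_000, rng)
cs2 = scenario.synth_cross_section(rates, 108.0, ages, 20_000, rng)

model = UndiagnosedDiseaseModel(cs1, cs2, mu=rates.mu, mu1=rates.mu1,
                                mu2=rates.mu2,
                                knots=np.arange(54.0, 87.0, 8.0),
                                eval_ages=np.arange(54.0, 87.0))
res = model.fit()
res.psa(n_draws=200, seed=1)
print(res.summary())
```

```
Undiagnosed-disease incidence reconstruction
  method: ls    reference time t' = 107
  X^2 = 55.6744    converged: True
   age  lambda0 /100py  lambda1 /100py     DR  sd0 /100py  sd1 /100py
54.000           1.152          23.841 20.701       0.089       1.864
62.000           1.385          25.225 18.219       0.101       1.635
70.000           1.641          25.412 15.485       0.119       1.929
78.000           2.029          28.683 14.134       0.151       2.298
86.000           1.807          21.254 11.760       0.185       3.059
```

The generating truth is `λ0` rising linearly from 1.2 to 2.0 per 100
person-years across ages 54–86 and a flat `λ1` of 25 per 100 person-years:
every estimate sits within about two standard deviations of it.  The DR
column says that at these survey conditions an undiagnosed case is 12–21
times more likely to be detected per year than a healthy person is to fall
ill — with the threshold Δ it determines whether the pool of undetected
cases is growing or shrinking.

A command-line interface mirrors the library (`undx simulate`,
`undx invert-direct`, `undx invert-ls`, `undx psa`, `undx detection-ratio`,
`undx fixtures`); every run writes a JSON manifest with its inputs, seed
and versions.

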