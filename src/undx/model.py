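"""High-level modelling interface in the estimator/results style.

:class:`UndiagnosedDiseaseModel` bundles the inverse problem — two
cross-sectional prevalence waves plus mortality — and ``fit`` returns an
:class:`UndiagnosedDiseaseResults` carrying the reconstructed onset and
detection rates, the detection ratio, uncertainty from probabilistic
sensitivity analysis, a text ``summary()`` and simple diagnostic plots.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import ConfigurationError
from .detection import detection_ratio
from .direct import CrossSection, IncidenceEstimate, direct_inverse
from .leastsq import (LSProblem, MortalityRiskTerm, PSAResult,
                      fit_rates, log_dr_uncertainty, run_psa)


class UndiagnosedDiseaseModel:
    """Inverse model for incidence of a partly undetected chronic disease.

    Parameters
    ----------
    cs1, cs2 : CrossSection
        Age-specific prevalence waves at times t1 < t2.
    mu, mu2 : callable, scalar, vector or UncertainValues
        General and diagnosed mortality rates at the reference time.
    mu1 : like mu, optional
        Undiagnosed mortality; omit it and pass ``mortality_risk`` to
        estimate it as a proportional multiple of the general mortality.
    t_prime : float, optional
        Reference time of the estimates (default: midpoint of the waves).
    knots : array, optional
        Knot ages of the piecewise-linear rate parameterisation used by the
        least-squares route.

    Examples
    --------
    >>> model = UndiagnosedDiseaseModel(cs1, cs2, mu=mu, mu1=mu1, mu2=mu2)
    >>> res = model.fit(method="ls")
    >>> res.params[["lambda0", "lambda1"]]
    """

    def __init__(self, cs1: CrossSection, cs2: CrossSection, mu, mu2,
                 mu1=None, t_prime: float | None = None, knots=None,
                 eval_ages=None, mortality_risk: MortalityRiskTerm | None = None,
                 sigma_mode: str = "auto"):
        self.problem = LSProblem(cs1=cs1, cs2=cs2, mu=mu, mu1=mu1, mu2=mu2,
                                 t_prime=t_prime, knots=knots,
                                 eval_ages=eval_ages, sigma_mode=sigma_mode,
                                 mortality_risk=mortality_risk)

    @classmethod
    def from_dataframes(cls, wave1: pd.DataFrame, wave2: pd.DataFrame,
                        t1: float, t2: float, mortality: pd.DataFrame,
                        **kwargs) -> "UndiagnosedDiseaseModel":
        """Build from tidy frames (a, p1, se1, p2, se2[, n]) and a
        mortality frame (a, mu, mu1, mu2)."""
        def _cs(df, t):
            kw = {k: df[k].to_numpy(float) for k in ("se1", "se2", "n")
                  if k in df.columns}
            return CrossSection(t=t, ages=df["a"].to_numpy(float),
                                p1=df["p1"].to_numpy(float),
                                p2=df["p2"].to_numpy(float), **kw)

        from .leastsq import UncertainValues

        ages = mortality["a"].to_numpy(float)

        def _uv(col):
            se = mortality[f"se_{col}"].to_numpy(float) \
                if f"se_{col}" in mortality.columns else None
            return UncertainValues(ages, mortality[col].to_numpy(float), se=se)

        return cls(_cs(wave1, t1), _cs(wave2, t2), mu=_uv("mu"),
                   mu1=_uv("mu1") if "mu1" in mortality.columns else None,
                   mu2=_uv("mu2"), **kwargs)

    def fit(self, method: str = "ls", **options) -> "UndiagnosedDiseaseResults":
        """Fit by weighted least squares (``"ls"``) or the closed-form
        direct route (``"direct"``)."""
        p = self.problem
        if method == "ls":
            est = fit_rates(p, **options)
        elif method == "direct":
            if p.estimates_r:
                raise ConfigurationError(
                    "the direct route needs an explicit mu1")
            from .leastsq import _mortality_values

            ages = options.pop("ages", p.knots)
            ages = np.asarray(ages, dtype=float)
            est = direct_inverse(
                p.cs1, p.cs2,
                mu=_mortality_values(p.mu, p, ages, "mu"),
                mu1=_mortality_values(p.mu1, p, ages, "mu1"),
                mu2=_mortality_values(p.mu2, p, ages, "mu2"),
                t_prime=p.t_prime, ages=ages, **options)
        else:
            raise ConfigurationError("method must be 'ls' or 'direct'")
        return UndiagnosedDiseaseResults(model=self, estimate=est,
                                         method=method)


@dataclasses.dataclass
class UndiagnosedDiseaseResults:
    """Reconstructed rates with uncertainty, detection ratio and summaries."""

    model: UndiagnosedDiseaseModel
    estimate: IncidenceEstimate
    method: str
    psa_result: PSAResult | None = None

    @property
    def ages(self):
        return self.estimate.ages

    @property
    def params(self) -> pd.DataFrame:
        """Point estimates per age: lambda0, lambda1, DR (per person-year)."""
        return pd.DataFrame({
            "a": self.estimate.ages,
            "lambda0": self.estimate.lambda0,
            "lambda1": self.estimate.lambda1,
            "dr": detection_ratio(self.estimate.lambda0, self.estimate.lambda1),
        }).set_index("a")

    @property
    def bse(self) -> pd.DataFrame:
        """Empirical standard deviations from the sensitivity analysis."""
        if self.psa_result is None:
            raise ConfigurationError("run .psa() first")
        return pd.DataFrame({
            "a": self.psa_result.ages,
            "sd_lambda0": self.psa_result.sd_lambda0,
            "sd_lambda1": self.psa_result.sd_lambda1,
        }).set_index("a")

    def psa(self, n_draws: int = 1000, seed: int = 0) -> PSAResult:
        """Propagate input uncertainty by resampling and refitting."""
        if self.method != "ls":
            raise ConfigurationError("sensitivity analysis applies to the "
                                     "least-squares route")
        self.psa_result = run_psa(self.model.problem, n_draws=n_draws,
                                  seed=seed)
        self.estimate.sd_lambda0 = self.psa_result.sd_lambda0
        self.estimate.sd_lambda1 = self.psa_result.sd_lambda1
        return self.psa_result

    def log_dr(self):
        """Log detection-ratio mean/SD per age (requires .psa())."""
        if self.psa_result is None:
            raise ConfigurationError("run .psa() first")
        return log_dr_uncertainty(self.psa_result)

    def summary(self) -> str:
        """Human-readable estimate table (rates per 100 person-years)."""
        lines = [
            "Undiagnosed-disease incidence reconstruction",
            f"  method: {self.method}    reference time t' = "
            f"{self.estimate.t_prime:g}",
        ]
        if self.method == "ls":
            lines.append(f"  X^2 = {self.estimate.meta['X2']:.6g}    "
                         f"converged: {self.estimate.meta['converged']}")
            if self.estimate.meta.get("R") is not None:
                lines.append(f"  mortality proportionality R = "
                             f"{self.estimate.meta['R']:.3f}")
        frame = pd.DataFrame({
            "age": self.estimate.ages,
            "lambda0 /100py": 100 * self.estimate.lambda0,
            "lambda1 /100py": 100 * self.estimate.lambda1,
            "DR": detection_ratio(self.estimate.lambda0, self.estimate.lambda1),
        })
        if self.psa_result is not None:
            frame["sd0 /100py"] = 100 * self.psa_result.sd_lambda0
            frame["sd1 /100py"] = 100 * self.psa_result.sd_lambda1
        lines.append(frame.to_string(index=False, float_format="%.3f"))
        return "\n".join(lines)

    def plot_rates(self, ax=None, truth=None):
        """Age profiles of the reconstructed rates (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ages, 100 * self.estimate.lambda0, "o-",
                label=r"$\lambda_0$ (onset)")
        ax.plot(self.ages, 100 * self.estimate.lambda1, "s-",
                label=r"$\lambda_1$ (detection)")
        if truth is not None:
            ax.plot(self.ages, 100 * np.asarray(truth[0]), "--", color="gray")
            ax.plot(self.ages, 100 * np.asarray(truth[1]), ":", color="gray")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("rate per 100 person-years")
        ax.set_yscale("log")
        ax.legend()
        return ax
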