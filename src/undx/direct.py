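"""Closed-form reconstruction of transition rates from two prevalence waves.

Solving the diagnosed-state transport equation for the detection rate gives,
for p1 > 0,

    lambda1 = [ (d_t + d_a) p2 + (mu2 - mu) p2 ] / p1,

and with lambda1 known the undiagnosed-state equation yields, for
1 - p1 - p2 > 0,

    lambda0 = [ (d_t + d_a) p1 + (lambda1 + mu1 - mu) p1 ] / (1 - p1 - p2).

The characteristic derivative is approximated from two cross-sectional
surveys at times t1 < t' < t2 by the first-order shift

    (d_t + d_a) p_k(t', a)  ~=  [ p_k(t2, a + t2 - t')
                                  - p_k(t1, a - t' + t1) ] / (t2 - t1),

interpolating linearly between tabulated survey ages.  Negative raw
estimates (possible with noisy input) are reported as-is and flagged; a
clamped view is available via :meth:`IncidenceEstimate.sanitized`.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .core import ConfigurationError, DomainError, SupportError

DEFAULT_EPS = 1e-6
"""Default guard for denominators p1 and 1 - p1 - p2."""


@dataclasses.dataclass
class CrossSection:
    """One cross-sectional survey wave of age-specific prevalences.

    Parameters
    ----------
    t : float
        Survey time (years since epoch).
    ages : array
        Strictly increasing ages at which prevalences are tabulated.
    p1, p2 : array
        Estimated proportions undiagnosed / diagnosed, with p1 + p2 <= 1.
    se1, se2 : array, optional
        Standard errors of p1 and p2.
    n : array, optional
        Per-age sample sizes.  If standard errors are missing but n is
        present, binomial standard errors sqrt(p(1-p)/n) are filled in.
    """

    t: float
    ages: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    se1: np.ndarray | None = None
    se2: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        if self.ages.ndim != 1:
            raise ConfigurationError("ages must be one-dimensional")
        if np.any(np.diff(self.ages) <= 0):
            raise ConfigurationError("ages must be strictly increasing")
        for name in ("p1", "p2"):
            arr = getattr(self, name)
            if arr.shape != self.ages.shape:
                raise ConfigurationError(f"{name} must match ages in length")
            if np.any(arr < 0) or np.any(arr > 1):
                raise DomainError(f"{name} must lie in [0, 1]")
        if np.any(self.p1 + self.p2 > 1 + 1e-9):
            raise DomainError("p1 + p2 must not exceed 1")
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=float)
            if self.se1 is None:
                self.se1 = np.sqrt(self.p1 * (1 - self.p1) / self.n)
            if self.se2 is None:
                self.se2 = np.sqrt(self.p2 * (1 - self.p2) / self.n)
        for name in ("se1", "se2"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if np.any(arr < 0):
                    raise DomainError(f"{name} must be nonnegative")
                setattr(self, name, arr)

    def _interp(self, values, age):
        age = np.asarray(age, dtype=float)
        lo, hi = self.ages[0], self.ages[-1]
        bad = (age < lo - 1e-9) | (age > hi + 1e-9)
        if np.any(bad):
            raise SupportError(
                f"ages {np.atleast_1d(age)[np.atleast_1d(bad)]} outside the "
                f"support [{lo}, {hi}] of the wave at t={self.t}")
        return np.interp(age, self.ages, values)

    def p1_at(self, age):
        return self._interp(self.p1, age)

    def p2_at(self, age):
        return self._interp(self.p2, age)

    def se1_at(self, age):
        if self.se1 is None:
            raise ConfigurationError(f"wave t={self.t} carries no se1")
        return self._interp(self.se1, age)

    def se2_at(self, age):
        if self.se2 is None:
            raise ConfigurationError(f"wave t={self.t} carries no se2")
        return self._interp(self.se2, age)

    def to_frame(self) -> pd.DataFrame:
        data = {"a": self.ages, "p1": self.p1, "p2": self.p2}
        if self.se1 is not None:
            data["se1"] = self.se1
        if self.se2 is not None:
            data["se2"] = self.se2
        if self.n is not None:
            data["n"] = self.n
        return pd.DataFrame(data)


class EstimateFlag(enum.IntFlag):
    """Per-age quality flags for reconstructed rates."""

    OK = 0
    P1_TOO_SMALL = 1        # lambda1 undefined: undiagnosed pool ~ empty
    P0_TOO_SMALL = 2        # lambda0 undefined: healthy pool ~ empty
    NEGATIVE_LAMBDA1 = 4
    NEGATIVE_LAMBDA0 = 8


@dataclasses.dataclass
class IncidenceEstimate:
    """Reconstructed onset (lambda0) and detection (lambda1) rates by age.

    Rates are per person-year at the reference time ``t_prime``.  Undefined
    entries are NaN and carry a flag; negative raw values are kept (with a
    flag) so that problems remain diagnosable.
    """

    t_prime: float
    ages: np.ndarray
    lambda0: np.ndarray
    lambda1: np.ndarray
    flags: np.ndarray
    sd_lambda0: np.ndarray | None = None
    sd_lambda1: np.ndarray | None = None
    cov_log: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def sanitized(self) -> "IncidenceEstimate":
        """Copy with negative rate estimates clamped to zero."""
        return dataclasses.replace(
            self,
            lambda0=np.where(np.isnan(self.lambda0), np.nan,
                             np.maximum(self.lambda0, 0.0)),
            lambda1=np.where(np.isnan(self.lambda1), np.nan,
                             np.maximum(self.lambda1, 0.0)))

    def to_frame(self) -> pd.DataFrame:
        data = {"a": self.ages, "lambda0": self.lambda0,
                "lambda1": self.lambda1, "flags": self.flags.astype(int)}
        if self.sd_lambda0 is not None:
            data["sd_lambda0"] = self.sd_lambda0
        if self.sd_lambda1 is not None:
            data["sd_lambda1"] = self.sd_lambda1
        return pd.DataFrame(data)


def characteristic_derivative(cs1: CrossSection, cs2: CrossSection,
                              t_prime: float, ages):
    """First-order characteristic derivative of (p1, p2) at (t', a).

    Returns ``(d1, d2)``, the rates of change of the two prevalences along
    the aging direction, computed from the two waves by the linearised
    shift; exact for fields affine in (t, a).
    """
    t1, t2 = cs1.t, cs2.t
    if not (t1 < t_prime < t2):
        raise ConfigurationError(
            f"need t1 < t' < t2, got {t1}, {t_prime}, {t2}")
    ages = np.asarray(ages, dtype=float)
    a_fwd = ages + (t2 - t_prime)
    a_bwd = ages - (t_prime - t1)
    d1 = (cs2.p1_at(a_fwd) - cs1.p1_at(a_bwd)) / (t2 - t1)
    d2 = (cs2.p2_at(a_fwd) - cs1.p2_at(a_bwd)) / (t2 - t1)
    return d1, d2


def midpoint_prevalence(cs1: CrossSection, cs2: CrossSection,
                        t_prime: float, ages):
    """Estimate (p1, p2) at the reference time t' from the two waves.

    Weighted average along the characteristic:
    p_k(t', a) ~= h2/(h1+h2) p_k(t1, a-h1) + h1/(h1+h2) p_k(t2, a+h2),
    with h1 = t'-t1, h2 = t2-t'.
    """
    h1 = t_prime - cs1.t
    h2 = cs2.t - t_prime
    if h1 <= 0 or h2 <= 0:
        raise ConfigurationError("t' must lie strictly between the waves")
    ages = np.asarray(ages, dtype=float)
    w1 = h2 / (h1 + h2)
    p1 = w1 * cs1.p1_at(ages - h1) + (1 - w1) * cs2.p1_at(ages + h2)
    p2 = w1 * cs1.p2_at(ages - h1) + (1 - w1) * cs2.p2_at(ages + h2)
    return p1, p2


def estimate_lambda1(p1, p2, deriv2, mu, mu2, eps: float = DEFAULT_EPS):
    """Detection rate from the diagnosed-state balance.

    Returns ``(lambda1, flags)``; entries with p1 <= eps are NaN and
    flagged rather than raising, so batch evaluation can proceed.
    """
    p1, p2, deriv2, mu, mu2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (p1, p2, deriv2, mu, mu2)))
    flags = np.zeros(p1.shape, dtype=int)
    ok = p1 > eps
    lam1 = np.full(p1.shape, np.nan)
    lam1[ok] = (deriv2[ok] + (mu2[ok] - mu[ok]) * p2[ok]) / p1[ok]
    flags[~ok] |= EstimateFlag.P1_TOO_SMALL
    flags[ok & (lam1 < 0)] |= EstimateFlag.NEGATIVE_LAMBDA1
    return lam1, flags


def estimate_lambda0(p1, p2, deriv1, lambda1, mu, mu1,
                     eps: float = DEFAULT_EPS):
    """Onset rate from the undiagnosed-state balance, given lambda1.

    Returns ``(lambda0, flags)``; entries with 1 - p1 - p2 <= eps or with
    undefined lambda1 are NaN and flagged.
    """
    p1, p2, deriv1, lambda1, mu, mu1 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float)
          for x in (p1, p2, deriv1, lambda1, mu, mu1)))
    flags = np.zeros(p1.shape, dtype=int)
    p0 = 1.0 - p1 - p2
    ok = (p0 > eps) & np.isfinite(lambda1)
    lam0 = np.full(p1.shape, np.nan)
    lam0[ok] = (deriv1[ok] + (lambda1[ok] + mu1[ok] - mu[ok]) * p1[ok]) / p0[ok]
    flags[p0 <= eps] |= EstimateFlag.P0_TOO_SMALL
    flags[ok & (lam0 < 0)] |= EstimateFlag.NEGATIVE_LAMBDA0
    return lam0, flags


def _mortality_at(m, t_prime, ages, name):
    """Normalise a mortality input (callable, scalar or vector) to per-age values."""
    if callable(m):
        return np.asarray(m(np.full(ages.shape, t_prime), ages), dtype=float)
    arr = np.asarray(m, dtype=float)
    if arr.ndim == 0:
        return np.full(ages.shape, float(arr))
    if arr.shape == ages.shape:
        return arr
    raise ConfigurationError(
        f"{name} must be a callable (t, a), a scalar, or a vector aligned "
        f"with the requested ages")


def default_ages(cs1: CrossSection, cs2: CrossSection, t_prime: float):
    """Reference-time ages at which both shifted survey ages are in support."""
    h1 = t_prime - cs1.t
    h2 = cs2.t - t_prime
    cand = cs1.ages + h1
    keep = (cand + h2 >= cs2.ages[0] - 1e-9) & (cand + h2 <= cs2.ages[-1] + 1e-9)
    return cand[keep]


def direct_inverse(cs1: CrossSection, cs2: CrossSection,
                   mu, mu1, mu2, t_prime: float | None = None,
                   ages=None, p_tprime=None,
                   eps: float = DEFAULT_EPS) -> IncidenceEstimate:
    """Closed-form inverse solution from two cross-sections plus mortality.

    Parameters
    ----------
    cs1, cs2 : CrossSection
        Survey waves at times t1 < t2.
    mu, mu1, mu2 : callable, scalar or vector
        General, undiagnosed and diagnosed mortality at the reference time.
    t_prime : float, optional
        Reference time; defaults to the midpoint (t1 + t2) / 2.
    ages : array, optional
        Ages at which to reconstruct the rates; default is every wave-1 age
        shifted to t' that stays within both waves' support.
    p_tprime : pair of arrays, optional
        Known prevalences (p1, p2) at (t', ages), e.g. from a forward
        solution in a simulation experiment.  If omitted they are estimated
        from the two waves by the characteristic midpoint average.
    """
    if t_prime is None:
        t_prime = 0.5 * (cs1.t + cs2.t)
    ages = default_ages(cs1, cs2, t_prime) if ages is None \
        else np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise DomainError("no ages with support in both waves")

    d1, d2 = characteristic_derivative(cs1, cs2, t_prime, ages)
    if p_tprime is None:
        p1, p2 = midpoint_prevalence(cs1, cs2, t_prime, ages)
    else:
        p1 = np.asarray(p_tprime[0], dtype=float)
        p2 = np.asarray(p_tprime[1], dtype=float)
        if p1.shape != ages.shape or p2.shape != ages.shape:
            raise ConfigurationError("p_tprime must align with ages")

    mu_a = _mortality_at(mu, t_prime, ages, "mu")
    mu1_a = _mortality_at(mu1, t_prime, ages, "mu1")
    mu2_a = _mortality_at(mu2, t_prime, ages, "mu2")

    lam1, f1 = estimate_lambda1(p1, p2, d2, mu_a, mu2_a, eps=eps)
    lam0, f0 = estimate_lambda0(p1, p2, d1, lam1, mu_a, mu1_a, eps=eps)
    flags = f0 | f1
    if np.all(np.isnan(lam0) & np.isnan(lam1)):
        raise DomainError(
            "direct inverse failed at every age "
            f"(flags: {[EstimateFlag(int(f)) for f in flags]})")
    return IncidenceEstimate(
        t_prime=float(t_prime), ages=ages, lambda0=lam0, lambda1=lam1,
        flags=flags,
        meta={"method": "direct", "t1": cs1.t, "t2": cs2.t,
              "p_tprime": "supplied" if p_tprime is not None else "midpoint"})
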