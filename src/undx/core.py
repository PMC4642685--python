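"""Shared domain types and elementary identities for the four-state model.

The population is partitioned into *Normal* (state 0), *Undiagnosed*
(state 1), *Diagnosed* (state 2) and *Dead*.  Transitions are
Normal -> Undiagnosed at rate ``lambda0(t, a)``, Undiagnosed -> Diagnosed
at rate ``lambda1(t, a)``, and death from state ``k`` at rate
``mu_k(t, a)``.  ``t`` is calendar time in years since an epoch
(the bundled scenario counts years since 1900-01-01) and ``a`` is age in
years.

Unit convention: every rate handled internally is an event rate per
person-year.  Tables published per 100 person-years are converted at the
I/O boundary (:func:`per100_to_rate` / :func:`rate_to_per100`).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable

import numpy as np

EPOCH_YEAR = 1900
"""Calendar year corresponding to t = 0 in the bundled scenario."""

#: absolute tolerance for the closure p0 + p1 + p2 = 1 on exact surfaces
CLOSURE_TOL = 1e-9


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ClosureError(ValueError):
    """State proportions do not sum to one within tolerance."""


class SupportError(ValueError):
    """A requested age/time lies outside the support of tabulated data."""


class InstabilityError(RuntimeError):
    """The integrator produced values outside [0, 1] beyond tolerance."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete configuration of a solver or problem."""


def per100_to_rate(x):
    """Convert a rate per 100 person-years to per person-year."""
    return np.asarray(x, dtype=float) / 100.0


def rate_to_per100(x):
    """Convert a rate per person-year to per 100 person-years."""
    return np.asarray(x, dtype=float) * 100.0


@dataclasses.dataclass(frozen=True)
class RateSurface:
    """A transition or mortality rate as a function of time and age.

    Wraps a vectorised callable ``fn(t, a) -> rate`` (per person-year)
    together with the (t, a) ranges on which it is valid.  Evaluation is
    deterministic and must be nonnegative on the valid ranges.
    """

    fn: Callable
    t_range: tuple = (-np.inf, np.inf)
    a_range: tuple = (0.0, np.inf)
    name: str = ""

    def __call__(self, t, a):
        t = np.asarray(t, dtype=float)
        a = np.asarray(a, dtype=float)
        try:
            value = np.asarray(self.fn(t, a), dtype=float)
        except Exception as exc:  # pragma: no cover - defensive
            raise DomainError(
                f"rate {self.name or '<anonymous>'} failed at "
                f"t={np.ravel(t)[:3]}, a={np.ravel(a)[:3]}: {exc}"
            ) from exc
        shape = np.broadcast_shapes(t.shape, a.shape)
        if value.shape != shape:
            value = np.broadcast_to(value, shape)
        return value

    @classmethod
    def constant(cls, value: float, name: str = "") -> "RateSurface":
        if value < 0:
            raise DomainError(f"constant rate must be >= 0, got {value}")
        return cls(fn=lambda t, a, _v=float(value): np.full(
            np.broadcast_shapes(np.shape(t), np.shape(a)), _v),
            name=name or f"const({value})")

    @classmethod
    def from_age_profile(cls, ages, values, name: str = "") -> "RateSurface":
        """Rate depending on age only, linear between tabulated ages,
        constant beyond the first/last age (``numpy.interp`` convention)."""
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages.ndim != 1 or ages.shape != values.shape:
            raise ConfigurationError("ages and values must be 1-d of equal length")
        if np.any(np.diff(ages) <= 0):
            raise ConfigurationError("ages must be strictly increasing")
        if np.any(values < 0):
            raise DomainError("tabulated rates must be nonnegative")

        def fn(t, a, _x=ages, _y=values):
            return np.interp(a, _x, _y)

        return cls(fn=fn, name=name)

    def scaled(self, factor: float, name: str = "") -> "RateSurface":
        if factor < 0:
            raise DomainError("scale factor must be nonnegative")
        return RateSurface(
            fn=lambda t, a, _f=float(factor): _f * self(t, a),
            t_range=self.t_range, a_range=self.a_range,
            name=name or f"{factor}*{self.name}")

    def check_nonnegative(self, t_values, a_values) -> None:
        """Probe the surface on a grid and raise if any value is negative."""
        tt, aa = np.meshgrid(np.asarray(t_values, float),
                             np.asarray(a_values, float), indexing="ij")
        v = self(tt, aa)
        if np.any(v < 0):
            i = np.argwhere(v < 0)[0]
            raise DomainError(
                f"rate {self.name} negative at t={tt[tuple(i)]}, a={aa[tuple(i)]}")


@dataclasses.dataclass(frozen=True)
class RateSet:
    """The five rate surfaces governing the model.

    ``mu`` is the overall (general-population) mortality; ``mu0`` (mortality
    of the healthy) is optional because the prevalence equations do not
    depend on it — it is only needed for absolute-count solutions and for
    consistency checks against the pooled illness-death equation.
    """

    lambda0: RateSurface
    lambda1: RateSurface
    mu: RateSurface
    mu1: RateSurface
    mu2: RateSurface
    mu0: RateSurface | None = None

    def __post_init__(self):
        for field in ("lambda0", "lambda1", "mu", "mu1", "mu2"):
            if getattr(self, field) is None:
                raise ConfigurationError(f"RateSet requires {field}")
        lo_t = max(r.t_range[0] for r in self._mandatory())
        hi_t = min(r.t_range[1] for r in self._mandatory())
        lo_a = max(r.a_range[0] for r in self._mandatory())
        hi_a = min(r.a_range[1] for r in self._mandatory())
        if lo_t >= hi_t or lo_a >= hi_a:
            raise ConfigurationError("rate surfaces have no common (t, a) domain")

    def _mandatory(self):
        return (self.lambda0, self.lambda1, self.mu, self.mu1, self.mu2)

    def with_mu0(self, mu0: RateSurface) -> "RateSet":
        return dataclasses.replace(self, mu0=mu0)


@dataclasses.dataclass(frozen=True)
class Grid:
    """Rectangular discretisation of the (t, a) plane with square step h."""

    t_min: float
    t_max: float
    a_min: float
    a_max: float
    h: float

    def __post_init__(self):
        if self.h <= 0:
            raise ConfigurationError("grid step h must be positive")
        if self.t_max <= self.t_min:
            raise ConfigurationError("t_max must exceed t_min")
        if not (self.a_max > self.a_min >= 0):
            raise ConfigurationError("need a_max > a_min >= 0")

    @property
    def t_nodes(self) -> np.ndarray:
        n = int(np.floor((self.t_max - self.t_min) / self.h + 1e-9)) + 1
        return self.t_min + self.h * np.arange(n)

    @property
    def a_nodes(self) -> np.ndarray:
        n = int(np.floor((self.a_max - self.a_min) / self.h + 1e-9)) + 1
        return self.a_min + self.h * np.arange(n)

    @property
    def shape(self) -> tuple:
        return (len(self.t_nodes), len(self.a_nodes))


@dataclasses.dataclass
class PrevalenceSurface:
    """Prevalences p1 (undiagnosed) and p2 (diagnosed) on a grid.

    Arrays are indexed ``[i_t, j_a]``.  Invariants: values in [0, 1],
    p1 + p2 <= 1 everywhere, and p1 = p2 = 0 at age 0.
    """

    grid: Grid
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        shape = self.grid.shape
        if self.p1.shape != shape or self.p2.shape != shape:
            raise ConfigurationError(
                f"prevalence arrays must have grid shape {shape}")
        tol = CLOSURE_TOL
        if (self.p1.min() < -tol or self.p2.min() < -tol
                or (self.p1 + self.p2).max() > 1 + tol):
            raise ClosureError("prevalences outside [0,1] or p1+p2 > 1")
        if abs(self.grid.a_min) < 1e-12:
            if np.any(np.abs(self.p1[:, 0]) > tol) or np.any(np.abs(self.p2[:, 0]) > tol):
                raise ClosureError("p1 and p2 must vanish at age 0")

    @property
    def p0(self) -> np.ndarray:
        return 1.0 - self.p1 - self.p2

    def at(self, t, a):
        """Bilinear interpolation of (p1, p2) at arbitrary points."""
        from scipy.interpolate import RegularGridInterpolator

        pts = np.column_stack([np.ravel(np.asarray(t, float)),
                               np.ravel(np.asarray(a, float))])
        out = []
        for arr in (self.p1, self.p2):
            f = RegularGridInterpolator(
                (self.grid.t_nodes, self.grid.a_nodes), arr)
            out.append(f(pts).reshape(np.broadcast_shapes(
                np.shape(t), np.shape(a))))
        return out[0], out[1]

    def to_frame(self):
        """Tidy long-format DataFrame with columns t, a, p1, p2, p0."""
        import pandas as pd

        tt, aa = np.meshgrid(self.grid.t_nodes, self.grid.a_nodes, indexing="ij")
        return pd.DataFrame({
            "t": tt.ravel(), "a": aa.ravel(),
            "p1": self.p1.ravel(), "p2": self.p2.ravel(),
            "p0": self.p0.ravel(),
        })


def prevalence_closure(ps: PrevalenceSurface) -> np.ndarray:
    """Proportion of healthy persons, p0 = 1 - p1 - p2, nodewise."""
    return ps.p0


def overall_mortality(p0, p1, p2, mu0, mu1, mu2, closure_tol: float = CLOSURE_TOL):
    """Overall mortality as the prevalence-weighted mix of state mortalities.

    mu = p0*mu0 + p1*mu1 + p2*mu2.  Raises :class:`ClosureError` if the
    proportions do not sum to one within ``closure_tol`` (use a looser
    tolerance for estimated survey proportions).
    """
    p0, p1, p2 = (np.asarray(x, dtype=float) for x in (p0, p1, p2))
    if np.any(np.abs(p0 + p1 + p2 - 1.0) > closure_tol):
        raise ClosureError("p0 + p1 + p2 must equal 1 within tolerance")
    for name, m in (("mu0", mu0), ("mu1", mu1), ("mu2", mu2)):
        if np.any(np.asarray(m, dtype=float) < 0):
            raise DomainError(f"{name} must be nonnegative")
    return p0 * np.asarray(mu0, float) + p1 * np.asarray(mu1, float) \
        + p2 * np.asarray(mu2, float)


def infer_mu0(mu, mu1, mu2, p1, p2):
    """Back out the mortality of the healthy from the overall mortality.

    Inverts the decomposition mu = p0*mu0 + p1*mu1 + p2*mu2 for mu0, with
    p0 = 1 - p1 - p2.  Requires p0 > 0; a negative result (inconsistent
    inputs) is returned as-is with a warning.
    """
    mu, mu1, mu2, p1, p2 = (np.asarray(x, dtype=float)
                            for x in (mu, mu1, mu2, p1, p2))
    p0 = 1.0 - p1 - p2
    if np.any(p0 <= 0):
        raise DomainError("infer_mu0 requires p0 = 1 - p1 - p2 > 0")
    mu0 = (mu - p1 * mu1 - p2 * mu2) / p0
    if np.any(mu0 < 0):
        warnings.warn("infer_mu0 produced negative values; the supplied "
                      "mortalities and prevalences are mutually inconsistent",
                      RuntimeWarning, stacklevel=2)
    return mu0
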