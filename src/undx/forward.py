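"""Forward solver for the age-structured compartment model.

The prevalences of the undiagnosed (p1) and diagnosed (p2) states obey the
coupled transport equations

    (d_t + d_a) p1 = -(lambda0 + lambda1 + mu1 - mu) p1 - lambda0 p2 + lambda0
    (d_t + d_a) p2 = lambda1 p1 - (mu2 - mu) p2

with p1(t, 0) = p2(t, 0) = 0 for every t.  Along a characteristic line of
constant birth time b = t - a the system reduces to an ordinary ODE in age,
which is integrated here with classical fourth-order Runge-Kutta.  Every
node is integrated from age 0 of its own birth cohort, so no initial age
profile at t_min is needed and the age-0 boundary condition holds exactly.

The absolute-count formulation (N0, N1, N2 with a newborn supply S0) is
provided for cross-checks; the two formulations agree through
N_k / (N0 + N1 + N2) when the overall mortality is the prevalence-weighted
mix of the state mortalities.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .core import (ConfigurationError, DomainError, Grid, InstabilityError,
                   PrevalenceSurface, RateSet, infer_mu0)

DEFAULT_STEP = 0.25
"""Default Runge-Kutta step along characteristics, in years."""

_CLIP_TOL = 1e-9   # excursions beyond [0,1] up to this size are clipped
_FAIL_TOL = 1e-6   # larger excursions abort with an instability error


def pde_rhs(lam0, lam1, mu, mu1, mu2, p1, p2):
    """Right-hand sides of the prevalence transport equations.

    All arguments broadcast; returns ``(f1, f2)`` with
    f1 = -(lam0+lam1+mu1-mu) p1 - lam0 p2 + lam0 and
    f2 = lam1 p1 - (mu2-mu) p2.
    """
    f1 = -(lam0 + lam1 + mu1 - mu) * p1 - lam0 * p2 + lam0
    f2 = lam1 * p1 - (mu2 - mu) * p2
    return f1, f2


def _rates_at(rates: RateSet, t, a):
    return (rates.lambda0(t, a), rates.lambda1(t, a), rates.mu(t, a),
            rates.mu1(t, a), rates.mu2(t, a))


def _prevalence_rhs(rates: RateSet, t, a, p1, p2):
    lam0, lam1, mu, mu1, mu2 = _rates_at(rates, t, a)
    return pde_rhs(lam0, lam1, mu, mu1, mu2, p1, p2)


def _integrate(rhs: Callable, birth, ages, step, y0):
    """RK4 march of ``y' = rhs(t, a, *y)`` along characteristics.

    ``birth`` and ``ages`` are equal-length vectors: cohort i starts at
    (t, a) = (birth[i], 0) with state ``y0[i]`` and is integrated to age
    ``ages[i]``.  Per-cohort step sizes divide the target age exactly and
    are as close to ``step`` as possible, which keeps node-aligned rate
    discontinuities (e.g. a disease-discovery year) at step boundaries
    whenever birth times and ages share the step's alignment.
    """
    birth = np.atleast_1d(np.asarray(birth, dtype=float))
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if birth.shape != ages.shape:
        raise ConfigurationError("birth and ages must have equal shape")
    if np.any(ages < 0):
        raise DomainError("ages must be nonnegative")

    n_state = len(y0)
    y = [np.array(np.broadcast_to(np.asarray(c, float), ages.shape), float)
         for c in y0]

    nsteps = np.zeros(ages.shape, dtype=int)
    pos = ages > 0
    nsteps[pos] = np.ceil(ages[pos] / step - 1e-9).astype(int)
    dt = np.zeros_like(ages)
    dt[pos] = ages[pos] / nsteps[pos]
    s = np.zeros_like(ages)

    for j in range(int(nsteps.max(initial=0))):
        act = nsteps > j
        h = dt[act]
        t0 = birth[act] + s[act]
        a0 = s[act]
        ycur = [c[act] for c in y]

        k1 = rhs(t0, a0, *ycur)
        k2 = rhs(t0 + h / 2, a0 + h / 2,
                 *[c + h / 2 * k for c, k in zip(ycur, k1)])
        k3 = rhs(t0 + h / 2, a0 + h / 2,
                 *[c + h / 2 * k for c, k in zip(ycur, k2)])
        k4 = rhs(t0 + h, a0 + h,
                 *[c + h * k for c, k in zip(ycur, k3)])
        ynew = [c + h / 6 * (a + 2 * b + 2 * cc + d)
                for c, a, b, cc, d in zip(ycur, k1, k2, k3, k4)]

        for idx in range(n_state):
            y[idx][act] = ynew[idx]
        s[act] += h
    return y


def prevalence_at(rates: RateSet, t: float, ages, step: float = DEFAULT_STEP):
    """Exact-characteristic prevalences (p1, p2) at a fixed time ``t``.

    Integrates one characteristic per requested age, from birth at t - a.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    birth = float(t) - ages
    p1, p2 = _integrate(lambda tt, aa, u, v: _prevalence_rhs(rates, tt, aa, u, v),
                        birth, ages, step, (0.0, 0.0))
    _check_bounds(p1, p2, t)
    return np.clip(p1, 0.0, 1.0), np.clip(p2, 0.0, 1.0)


def cross_section_at(rates: RateSet, t: float, ages,
                     step: float = DEFAULT_STEP):
    """Noise-free survey wave taken from the exact forward solution."""
    from .direct import CrossSection

    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    p1, p2 = prevalence_at(rates, t, ages, step=step)
    return CrossSection(t=float(t), ages=ages, p1=p1, p2=p2)


def _check_bounds(p1, p2, where):
    worst = max(float(-p1.min(initial=0.0)), float(-p2.min(initial=0.0)),
                float((p1 + p2).max(initial=0.0) - 1.0))
    if worst > _FAIL_TOL:
        raise InstabilityError(
            f"prevalence left [0,1] by {worst:.2e} near t={where}; "
            "reduce the integration step")


def solve_forward(rates: RateSet, grid: Grid,
                  step: float = DEFAULT_STEP) -> PrevalenceSurface:
    """Solve the prevalence system on every node of ``grid``.

    Each node (t, a) is obtained by integrating its own birth cohort from
    age 0, so the rates must be evaluable on the hull of characteristics,
    i.e. for times back to ``t_min - a_max``.
    """
    t_nodes, a_nodes = grid.t_nodes, grid.a_nodes
    _check_hull(rates, t_nodes, a_nodes)
    tt, aa = np.meshgrid(t_nodes, a_nodes, indexing="ij")
    birth = (tt - aa).ravel()
    ages = aa.ravel()
    p1, p2 = _integrate(lambda t, a, u, v: _prevalence_rhs(rates, t, a, u, v),
                        birth, ages, step, (0.0, 0.0))
    _check_bounds(p1, p2, f"grid [{grid.t_min},{grid.t_max}]")
    p1 = np.clip(p1, 0.0, 1.0).reshape(tt.shape)
    p2 = np.clip(p2, 0.0, 1.0).reshape(tt.shape)
    return PrevalenceSurface(grid=grid, p1=p1, p2=p2)


def _check_hull(rates: RateSet, t_nodes, a_nodes):
    t_lo = float(t_nodes.min() - a_nodes.max())
    t_hi = float(t_nodes.max())
    a_hi = float(a_nodes.max())
    for name in ("lambda0", "lambda1", "mu", "mu1", "mu2"):
        surf = getattr(rates, name)
        if surf.t_range[0] > t_lo or surf.t_range[1] < t_hi \
                or surf.a_range[0] > 0 or surf.a_range[1] < a_hi:
            raise DomainError(
                f"rate {name} is not valid on the characteristic hull "
                f"t in [{t_lo}, {t_hi}], a in [0, {a_hi}]")


@dataclasses.dataclass
class CountSurface:
    """Absolute state counts N0, N1, N2 on a grid, plus the newborn supply."""

    grid: Grid
    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    s0: Callable

    def __post_init__(self):
        if min(self.n0.min(), self.n1.min(), self.n2.min()) < -1e-9:
            raise InstabilityError("negative counts")

    @property
    def total(self) -> np.ndarray:
        return self.n0 + self.n1 + self.n2

    def prevalences(self) -> PrevalenceSurface:
        """Derived prevalence surface N_k / N (N must be positive)."""
        n = self.total
        if np.any(n <= 0):
            raise DomainError("total population must be positive")
        return PrevalenceSurface(grid=self.grid,
                                 p1=np.clip(self.n1 / n, 0, 1),
                                 p2=np.clip(self.n2 / n, 0, 1))


def solve_counts(rates: RateSet, s0: Callable, grid: Grid,
                 step: float = DEFAULT_STEP) -> CountSurface:
    """Solve the absolute-count system for (N0, N1, N2).

    Requires ``rates.mu0``.  ``s0(t)`` is the number of healthy newborns at
    calendar time t (N0(t, 0) = S0(t), N1 = N2 = 0 at age 0).
    """
    if rates.mu0 is None:
        raise ConfigurationError("solve_counts requires RateSet.mu0")
    t_nodes, a_nodes = grid.t_nodes, grid.a_nodes
    tt, aa = np.meshgrid(t_nodes, a_nodes, indexing="ij")
    birth = (tt - aa).ravel()
    ages = aa.ravel()
    supply = np.asarray(s0(birth), dtype=float)
    if np.any(supply < 0):
        raise DomainError("newborn supply S0 must be nonnegative")

    def rhs(t, a, n0v, n1v, n2v):
        lam0, lam1, mu, mu1, mu2 = _rates_at(rates, t, a)
        mu0 = rates.mu0(t, a)
        return (-(mu0 + lam0) * n0v,
                -(mu1 + lam1) * n1v + lam0 * n0v,
                -mu2 * n2v + lam1 * n1v)

    n0, n1, n2 = _integrate(rhs, birth, ages, step,
                            (supply, np.zeros_like(supply), np.zeros_like(supply)))
    shape = tt.shape
    return CountSurface(grid=grid, n0=np.maximum(n0, 0).reshape(shape),
                        n1=np.maximum(n1, 0).reshape(shape),
                        n2=np.maximum(n2, 0).reshape(shape), s0=s0)


@dataclasses.dataclass(frozen=True)
class ConsistencyReport:
    """Residual of the pooled illness-death equation on the grid interior."""

    residual: np.ndarray
    max_abs: float


def check_illness_death_consistency(ps: PrevalenceSurface,
                                    rates: RateSet) -> ConsistencyReport:
    """Residual of the conventional illness-death equation for p = p1 + p2.

    Pooling the two disease states must satisfy
    (d_t + d_a) p = (1 - p) [lambda0 - (mu - mu0)], with mu0 recovered from
    the mortality decomposition.  The characteristic derivative is taken by
    the forward difference [p(t+h, a+h) - p(t, a)] / h, so the residual is
    a first-order diagnostic: it shrinks like O(h) under grid refinement.
    """
    g = ps.grid
    h = g.h
    p = ps.p1 + ps.p2
    tt, aa = np.meshgrid(g.t_nodes[:-1], g.a_nodes[:-1], indexing="ij")
    p_here = p[:-1, :-1]
    lhs = (p[1:, 1:] - p_here) / h
    lam0 = rates.lambda0(tt, aa)
    mu = rates.mu(tt, aa)
    mu1 = rates.mu1(tt, aa)
    mu2 = rates.mu2(tt, aa)
    mu0 = infer_mu0(mu, mu1, mu2, ps.p1[:-1, :-1], ps.p2[:-1, :-1])
    residual = lhs - (1.0 - p_here) * (lam0 - (mu - mu0))
    return ConsistencyReport(residual=residual,
                             max_abs=float(np.max(np.abs(residual))))
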