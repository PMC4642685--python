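"""Detection ratio and the growth threshold for undiagnosed prevalence.

The detection ratio DR(t, a) = lambda1 / lambda0 (a hazard ratio) compares
the intensity of diagnosing existing undiagnosed cases with the intensity
of new onsets.  Whether the undiagnosed prevalence p1 grows or shrinks
along the aging direction is decided by comparing DR with the threshold

    Delta(t, a) = p0 / p1 + (mu - mu1) / lambda0:

DR < Delta implies p1 increases along the characteristic, DR > Delta that
it decreases, and DR = Delta is the stationary case — this is exactly the
sign of the undiagnosed-state transport equation's right-hand side.
"""

from __future__ import annotations

import dataclasses

import numpy as np

VERDICTS = ("increasing", "decreasing", "stationary", "undefined")

#: relative tolerance inside which DR and Delta count as equal
STATIONARY_RTOL = 1e-8


def detection_ratio(lambda0, lambda1):
    """DR = lambda1 / lambda0; NaN (flagged-undefined) where lambda0 <= 0."""
    lambda0, lambda1 = np.broadcast_arrays(
        np.asarray(lambda0, dtype=float), np.asarray(lambda1, dtype=float))
    out = np.full(lambda0.shape, np.nan)
    ok = lambda0 > 0
    out[ok] = lambda1[ok] / lambda0[ok]
    return out


def dr_threshold(p0, p1, mu, mu1, lambda0):
    """Growth threshold Delta = p0/p1 + (mu - mu1)/lambda0.

    NaN where p1 <= 0 or lambda0 <= 0 (the threshold is only defined for a
    populated undiagnosed pool with ongoing onset).
    """
    p0, p1, mu, mu1, lambda0 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (p0, p1, mu, mu1, lambda0)))
    out = np.full(p0.shape, np.nan)
    ok = (p1 > 0) & (lambda0 > 0)
    out[ok] = p0[ok] / p1[ok] + (mu[ok] - mu1[ok]) / lambda0[ok]
    return out


def classify_trend(dr, delta, rtol: float = STATIONARY_RTOL):
    """Trend verdict for p1 along the characteristic from DR vs Delta."""
    dr, delta = np.broadcast_arrays(np.asarray(dr, dtype=float),
                                    np.asarray(delta, dtype=float))
    verdict = np.full(dr.shape, "undefined", dtype=object)
    defined = np.isfinite(dr) & np.isfinite(delta)
    scale = np.maximum.reduce([np.abs(dr), np.abs(delta),
                               np.ones_like(dr)])
    near = defined & (np.abs(dr - delta) <= rtol * scale)
    verdict[defined & (dr < delta) & ~near] = "increasing"
    verdict[defined & (dr > delta) & ~near] = "decreasing"
    verdict[near] = "stationary"
    return verdict


@dataclasses.dataclass(frozen=True)
class DetectionAssessment:
    """Detection ratio, threshold and trend verdict at points (t, a)."""

    t: np.ndarray
    a: np.ndarray
    dr: np.ndarray
    delta: np.ndarray
    verdict: np.ndarray


def assess(t, a, lambda0, lambda1, p0, p1, mu, mu1,
           rtol: float = STATIONARY_RTOL) -> DetectionAssessment:
    """Bundle DR, Delta and the trend verdict for given points and inputs."""
    dr = detection_ratio(lambda0, lambda1)
    delta = dr_threshold(p0, p1, mu, mu1, lambda0)
    return DetectionAssessment(
        t=np.asarray(t, dtype=float), a=np.asarray(a, dtype=float),
        dr=dr, delta=delta, verdict=classify_trend(dr, delta, rtol=rtol))
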