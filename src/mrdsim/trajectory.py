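"""Three-phase piecewise MRD trajectory model.

The true biomarker level of a subject follows three phases:

1. **Decay** (``0 <= t < te``): exponential decline from the baseline level
   ``beta0`` to the plateau level ``beta1``, reached exactly at the
   end-of-treatment time ``te``.  The decay rate ``k = ln(beta0/beta1)/te``
   is fully determined by the endpoints, so each subject's rate is
   individualized through their (beta0, beta1, te).
2. **Plateau** (``te <= t <= tr``): constant at ``beta1``.
3. **Relapse** (``t > tr``): exponential regrowth from the plateau at rate
   ``beta2``.  ``tr = +inf`` encodes a subject who never relapses.

All three pieces, the time derivative, and the running integral
(cumulative disease burden) have closed forms, which this module
implements; the log10-scale counterparts used by the hazard's log link are
piecewise *linear* and are provided too.  Observed values add Gaussian
measurement noise on top of the true curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TrajectoryParams",
    "mu",
    "dmu_dt",
    "cum_mu",
    "log10_mu",
    "dlog10_mu_dt",
    "cum_log10_mu",
    "observe",
]

LN10 = math.log(10.0)


class TrajectoryDomainError(ValueError):
    """Invalid trajectory parameter or evaluation point."""


@dataclass(frozen=True)
class TrajectoryParams:
    """Ground-truth curve parameters for one subject.

    Parameters
    ----------
    beta0 : float
        Baseline MRD level at treatment start (t=0).  Strictly positive;
        units (fraction, copies/mL, ...) are dataset metadata.
    beta1 : float
        Plateau MRD level reached at the end-of-treatment time.
    beta2 : float
        Exponential regrowth rate (1/time) after relapse onset.
    te : float
        End-of-treatment time; the decay phase ends here.
    tr : float
        Relapse onset time; ``math.inf`` means no relapse.  Must satisfy
        ``tr >= te``.
    sigma : float
        Standard deviation of the Gaussian measurement error.
    """

    beta0: float
    beta1: float
    beta2: float
    te: float
    tr: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "te"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise TrajectoryDomainError(
                    f"{name} must be finite and > 0, got {v!r}"
                )
        if not (math.isfinite(self.beta2) and self.beta2 >= 0):
            raise TrajectoryDomainError(
                f"beta2 must be finite and >= 0, got {self.beta2!r}"
            )
        if math.isnan(self.tr) or self.tr < self.te:
            raise TrajectoryDomainError(
                f"tr must be >= te ({self.te}) or +inf, got {self.tr!r}"
            )
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise TrajectoryDomainError(
                f"sigma must be finite and >= 0, got {self.sigma!r}"
            )

    @property
    def decay_rate(self) -> float:
        """k = ln(beta0/beta1)/te; zero when beta0 == beta1 (flat decay)."""
        return math.log(self.beta0 / self.beta1) / self.te


def _check_time(t: float) -> float:
    t = float(t)
    if math.isnan(t) or t < 0:
        raise TrajectoryDomainError(f"t must be a non-negative real, got {t!r}")
    return t


def mu(params: TrajectoryParams, t: float) -> float:
    """True trajectory value at time ``t`` (continuous, strictly positive)."""
    t = _check_time(t)
    if t < params.te:
        return params.beta0 * math.exp(-params.decay_rate * t)
    if t <= params.tr:
        return params.beta1
    return params.beta1 * math.exp(params.beta2 * (t - params.tr))


def dmu_dt(params: TrajectoryParams, t: float) -> float:
    """Time derivative of the trajectory.

    The curve has kinks at ``te`` and ``tr``; the *right-hand* one-sided
    derivative is returned there, so the slope at a boundary reflects the
    phase that is about to begin.
    """
    t = _check_time(t)
    if t < params.te:
        return -params.decay_rate * mu(params, t)
    if t < params.tr:
        return 0.0
    if t == params.tr:  # right-hand: start of relapse growth
        return params.beta2 * params.beta1
    return params.beta2 * mu(params, t)


def cum_mu(params: TrajectoryParams, t: float) -> float:
    """Running integral ``∫_0^t mu(s) ds`` assembled from closed-form pieces."""
    t = _check_time(t)
    k = params.decay_rate
    b0, b1 = params.beta0, params.beta1
    # decay contribution over [0, min(t, te)]
    td = min(t, params.te)
    if k == 0.0:
        total = b0 * td
    else:
        total = b0 * (1.0 - math.exp(-k * td)) / k
    if t <= params.te:
        return total
    # plateau over [te, min(t, tr)]
    total += b1 * (min(t, params.tr) - params.te)
    if t <= params.tr:
        return total
    # relapse over [tr, t]
    if params.beta2 == 0.0:
        total += b1 * (t - params.tr)
    else:
        total += b1 * (math.exp(params.beta2 * (t - params.tr)) - 1.0) / params.beta2
    return total


# ---------------------------------------------------------------------------
# log10-scale counterparts (piecewise linear) for the hazard's log link.


def log10_mu(params: TrajectoryParams, t: float) -> float:
    """log10 of the true trajectory; piecewise linear in t."""
    t = _check_time(t)
    if t < params.te:
        return math.log10(params.beta0) - (params.decay_rate / LN10) * t
    if t <= params.tr:
        return math.log10(params.beta1)
    return math.log10(params.beta1) + (params.beta2 / LN10) * (t - params.tr)


def dlog10_mu_dt(params: TrajectoryParams, t: float) -> float:
    """Derivative of log10 mu; piecewise constant, right-continuous at kinks."""
    t = _check_time(t)
    if t < params.te:
        return -params.decay_rate / LN10
    if t < params.tr:
        return 0.0
    return params.beta2 / LN10


def cum_log10_mu(params: TrajectoryParams, t: float) -> float:
    """∫_0^t log10 mu(s) ds — exact integral of the piecewise-linear curve."""
    t = _check_time(t)
    l0 = math.log10(params.beta0)
    l1 = math.log10(params.beta1)
    slope_d = -params.decay_rate / LN10
    td = min(t, params.te)
    total = l0 * td + 0.5 * slope_d * td * td
    if t <= params.te:
        return total
    total += l1 * (min(t, params.tr) - params.te)
    if t <= params.tr:
        return total
    dt = t - params.tr
    total += l1 * dt + 0.5 * (params.beta2 / LN10) * dt * dt
    return total


def observe(
    params: TrajectoryParams,
    times: Sequence[float],
    rng: np.random.Generator,
    noise_mode: Literal["additive", "multiplicative"] = "additive",
) -> list[tuple[float, float, float]]:
    """Sample noisy measurements of the trajectory.

    One draw per entry of ``times``, in order (the reproducibility
    contract).  In ``additive`` mode the observation is
    ``mu(t) + eps, eps ~ N(0, sigma^2)``, floored at zero because the
    biomarker is non-negative; in ``multiplicative`` mode it is
    ``mu(t) * exp(eps)``, which is positive by construction.

    Returns
    -------
    list of (time, value, raw_value)
        ``raw_value`` is the pre-floor draw (equal to ``value`` except when
        an additive draw went negative).
    """
    times = [(_check_time(t)) for t in times]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("observation times must be sorted ascending")
    if noise_mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    out: list[tuple[float, float, float]] = []
    for t in times:
        m = mu(params, t)
        eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
        if noise_mode == "additive":
            raw = m + eps
            out.append((t, max(raw, 0.0), raw))
        else:
            raw = m * math.exp(eps)
            out.append((t, raw, raw))
    return out
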