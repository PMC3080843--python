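"""Model core: steady-state sigmoids, vector field, dynamic a-nullcline, knees.

The activity equation is

    tau_a * da/dt = a_inf(w*s*a - g*theta) - a

where ``a_inf`` is an increasing logistic sigmoid with half-activation
input ``theta0`` and spread ``k_a``.  The slow processes relax toward their
activity-dependent steady states,

    ds/dt     = (s_inf(a) - s) / tau_s         (s_inf decreasing in a)
    dtheta/dt = (theta_inf(a) - theta) / tau_theta   (theta_inf increasing)

Projected onto the (a, s) plane the da/dt = 0 surface is an S-shaped
"dynamic a-nullcline" parameterized by the instantaneous theta; its folds
(low knee LK, high knee HK) are where the trajectory jumps between the
low- and high-activity branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .exceptions import DomainError, ParameterError
from .params import ModelParams, State

__all__ = [
    "steady_state",
    "a_inf",
    "s_inf",
    "theta_inf",
    "vector_field",
    "nullcline_s",
    "knee_condition_lhs",
    "find_knees",
    "KneeSet",
]


def steady_state(x, center: float, spread: float, increasing: bool = True):
    """Logistic sigmoid used for all three steady-state functions.

    Returns ``1 / (1 + exp(-(x - center)/spread))`` for an increasing
    sigmoid, and its mirror image for a decreasing one.  Strictly monotone,
    equals 1/2 at ``x = center``, with limits 0 and 1.

    Accepts scalars or numpy arrays.
    """
    if spread <= 0:
        raise ParameterError("sigmoid spread must be > 0")
    z = (np.asarray(x, dtype=float) - center) / spread
    if not increasing:
        z = -z
    out = 1.0 / (1.0 + np.exp(-z))
    if np.ndim(x) == 0:
        return float(out)
    return out


def a_inf(x, p: ModelParams):
    """Steady-state network output for total synaptic input ``x``."""
    return steady_state(x, p.theta0, p.k_a, increasing=True)


def s_inf(a, p: ModelParams):
    """Steady-state synaptic availability at activity ``a`` (decreasing)."""
    return steady_state(a, p.theta_s, p.k_s, increasing=False)


def theta_inf(a, p: ModelParams):
    """Steady-state adaptation at activity ``a`` (increasing)."""
    return steady_state(a, p.theta_theta, p.k_theta, increasing=True)


def vector_field(state: State, p: ModelParams) -> tuple[float, float, float]:
    """Time derivatives ``(da/dt, ds/dt, dtheta/dt)`` at ``state``.

    The recurrent input to the activity sigmoid is ``w*s*a``, reduced
    subtractively by the adaptation current ``g*theta``; with ``g = 0``
    theta has no influence on ``a``.
    """
    a, s, theta = state.a, state.s, state.theta
    da = (a_inf(p.w * s * a - p.g * theta, p) - a) / p.tau_a
    ds = (s_inf(a, p) - s) / p.tau_s
    dtheta = (theta_inf(a, p) - theta) / p.tau_theta
    return (da, ds, dtheta)


def nullcline_s(a, theta: float, p: ModelParams):
    """s-coordinate of the dynamic a-nullcline at activity ``a``.

    Inverts the activity sigmoid on da/dt = 0:

        s = (g*theta + theta0 + k_a * ln(a/(1-a))) / (w * a)

    ``a`` must lie strictly inside (0, 1).  Accepts scalars or arrays.
    """
    if p.w <= 0:
        raise ParameterError("nullcline requires w > 0")
    arr = np.asarray(a, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError("nullcline_s requires 0 < a < 1")
    s = (p.g * theta + p.theta0 + p.k_a * np.log(arr / (1.0 - arr))) / (p.w * arr)
    if np.ndim(a) == 0:
        return float(s)
    return s


def knee_condition_lhs(a):
    """Left side of the knee condition, ``1/(1-a) - ln(a/(1-a))``.

    Setting ds/da = 0 on the dynamic a-nullcline gives

        1/(1-a_k) - ln(a_k/(1-a_k)) = (g*theta + theta0) / k_a.

    The left side has its minimum, 2, at a = 1/2 and diverges at both ends
    of (0, 1), so two knees exist exactly when the right side exceeds 2.
    """
    arr = np.asarray(a, dtype=float)
    out = 1.0 / (1.0 - arr) - np.log(arr / (1.0 - arr))
    if np.ndim(a) == 0:
        return float(out)
    return out


#: Critical value of (g*theta + theta0)/k_a above which two knees exist.
KNEE_THRESHOLD = 2.0

_EPS = 1e-9  # bisection interval endpoint offset


@dataclass(frozen=True)
class KneeSet:
    """Knees of the dynamic a-nullcline at a fixed adaptation level.

    ``a_LK`` (< 1/2) and ``a_HK`` (> 1/2) are the activities of the low and
    high knee; ``s_LK``/``s_HK`` the corresponding nullcline s-values.
    ``exists`` is False when the knee condition's right side does not
    exceed 2, including the degenerate double root at exactly 2 (a
    degenerate knee cannot support a jump).
    """

    theta: float
    exists: bool
    a_LK: float | None = None
    a_HK: float | None = None
    s_LK: float | None = None
    s_HK: float | None = None


def find_knees(theta: float, p: ModelParams) -> KneeSet:
    """Locate the knees of the dynamic a-nullcline at adaptation ``theta``.

    Solves the knee condition by bisection on (eps, 1/2) and (1/2, 1-eps)
    to absolute tolerance 1e-10.  Non-existence (right side <= 2) is a
    valid result, not an error.
    """
    rhs = (p.g * theta + p.theta0) / p.k_a
    if rhs <= KNEE_THRESHOLD:
        return KneeSet(theta=theta, exists=False)

    def f(a: float) -> float:
        return 1.0 / (1.0 - a) - math.log(a / (1.0 - a)) - rhs

    # f > 0 at both interval ends, f(1/2) = 2 - rhs < 0; the tight xtol
    # keeps the condition residual below 1e-9 even where f is steep
    a_lk = bisect(f, _EPS, 0.5, xtol=1e-12)
    a_hk = bisect(f, 0.5, 1.0 - _EPS, xtol=1e-12)
    return KneeSet(
        theta=theta,
        exists=True,
        a_LK=a_lk,
        a_HK=a_hk,
        s_LK=nullcline_s(a_lk, theta, p),
        s_HK=nullcline_s(a_hk, theta, p),
    )
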