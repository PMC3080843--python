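"""Fixed-step RK4 integration, limit-cycle settling and crossing lookup.

The equations are solved with the classical 4th-order Runge-Kutta method
at a fixed step (dt = 0.05 by default).  No adaptive stepping is used:
determinism and reproducibility matter more than efficiency here, and the
relaxation dynamics are well resolved at this step.  The inner loop is
compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .episodes import DEFAULT_THRESHOLD, segment
from .exceptions import (AnalysisError, ConvergenceError, DivergenceError,
                         IntegrationError)
from .params import DEFAULT_INIT, ModelParams, State
from .trajectory import Trajectory, concatenate

__all__ = ["integrate", "settle", "SettleReport", "state_at_crossing",
           "first_crossing_time"]

#: Settling convergence: three consecutive periods agree to this relative tol.
PERIOD_RTOL = 1e-4
#: No complete episode within this horizon => rhythm lost.
NO_EPISODE_HORIZON = 40_000.0
#: Activity range below this over a whole window => rhythm lost.
FLATLINE_RANGE = 0.05
#: Hard cap on total settling time.
SETTLE_CAP = 400_000.0


@njit(cache=False)
def _rk4_kernel(a0, s0, th0, n_steps, dt,
                w, theta0, k_a, theta_s, k_s, tau_s,
                theta_th, k_th, tau_th, g, tau_a):  # pragma: no cover - compiled
    A = np.empty(n_steps + 1)
    S = np.empty(n_steps + 1)
    T = np.empty(n_steps + 1)
    a, s, th = a0, s0, th0
    A[0] = a
    S[0] = s
    T[0] = th
    for i in range(n_steps):
        # four stages, sigmoids inlined
        x = w * s * a - g * th
        da1 = (1.0 / (1.0 + math.exp(-(x - theta0) / k_a)) - a) / tau_a
        ds1 = (1.0 / (1.0 + math.exp((a - theta_s) / k_s)) - s) / tau_s
        dt1 = (1.0 / (1.0 + math.exp(-(a - theta_th) / k_th)) - th) / tau_th

        a2 = a + 0.5 * dt * da1
        s2 = s + 0.5 * dt * ds1
        t2 = th + 0.5 * dt * dt1
        x = w * s2 * a2 - g * t2
        da2 = (1.0 / (1.0 + math.exp(-(x - theta0) / k_a)) - a2) / tau_a
        ds2 = (1.0 / (1.0 + math.exp((a2 - theta_s) / k_s)) - s2) / tau_s
        dt2 = (1.0 / (1.0 + math.exp(-(a2 - theta_th) / k_th)) - t2) / tau_th

        a3 = a + 0.5 * dt * da2
        s3 = s + 0.5 * dt * ds2
        t3 = th + 0.5 * dt * dt2
        x = w * s3 * a3 - g * t3
        da3 = (1.0 / (1.0 + math.exp(-(x - theta0) / k_a)) - a3) / tau_a
        ds3 = (1.0 / (1.0 + math.exp((a3 - theta_s) / k_s)) - s3) / tau_s
        dt3 = (1.0 / (1.0 + math.exp(-(a3 - theta_th) / k_th)) - t3) / tau_th

        a4 = a + dt * da3
        s4 = s + dt * ds3
        t4 = th + dt * dt3
        x = w * s4 * a4 - g * t4
        da4 = (1.0 / (1.0 + math.exp(-(x - theta0) / k_a)) - a4) / tau_a
        ds4 = (1.0 / (1.0 + math.exp((a4 - theta_s) / k_s)) - s4) / tau_s
        dt4 = (1.0 / (1.0 + math.exp(-(a4 - theta_th) / k_th)) - t4) / tau_th

        a = a + dt * (da1 + 2.0 * da2 + 2.0 * da3 + da4) / 6.0
        s = s + dt * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4) / 6.0
        th = th + dt * (dt1 + 2.0 * dt2 + 2.0 * dt3 + dt4) / 6.0
        A[i + 1] = a
        S[i + 1] = s
        T[i + 1] = th
    return A, S, T


def integrate(p: ModelParams, init: State = DEFAULT_INIT,
              duration: float = 1000.0, dt: float | None = None,
              t0: float = 0.0) -> Trajectory:
    """Integrate the model for ``duration`` time units from ``init``.

    Deterministic given ``(p, init, duration, dt)``; the returned trajectory
    includes the initial state as its first sample.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    dt = p.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = max(int(round(duration / dt)), 1)
    A, S, T = _rk4_kernel(
        init.a, init.s, init.theta, n, dt,
        p.w, p.theta0, p.k_a, p.theta_s, p.k_s, p.tau_s,
        p.theta_theta, p.k_theta, p.tau_theta, p.g, p.tau_a,
    )
    if not (np.isfinite(A[-1]) and np.isfinite(S[-1]) and np.isfinite(T[-1])):
        bad = np.nonzero(~(np.isfinite(A) & np.isfinite(S) & np.isfinite(T)))[0]
        t_bad = t0 + bad[0] * dt
        raise IntegrationError(f"non-finite state at t = {t_bad}", t=t_bad)
    t = t0 + dt * np.arange(n + 1)
    return Trajectory(t=t, a=A, s=S, theta=T, dt=dt)


@dataclass(frozen=True)
class SettleReport:
    """Outcome of limit-cycle settling.

    ``converged`` and ``rhythm_lost`` are mutually exclusive;
    ``period_rel_change`` is the spread of the last three periods relative
    to their mean (NaN when fewer than three were seen).
    """

    converged: bool
    rhythm_lost: bool
    n_discarded_cycles: int
    period_rel_change: float
    final_state: State


def settle(p: ModelParams, init: State = DEFAULT_INIT,
           threshold: float = DEFAULT_THRESHOLD,
           ) -> tuple[Trajectory, SettleReport]:
    """Integrate until the rhythm converges to a limit cycle (or is lost).

    Integration proceeds in windows of ``20 * max(tau_s, tau_theta)`` time
    units, segmenting after each.  Convergence requires three consecutive
    full periods agreeing to relative tolerance 1e-4; the returned
    trajectory then spans exactly those three onset-to-onset cycles (with
    one bracketing sample on each side so boundary crossings remain
    interpolatable).  Rhythm loss is declared when no complete episode
    occurs within 40,000 time units, or the activity range over a whole
    window falls below 0.05.

    Raises
    ------
    ConvergenceError
        If neither outcome is reached within 400,000 time units.
    """
    window = 20.0 * max(p.tau_s, p.tau_theta)
    keep = max(3.0 * window, NO_EPISODE_HORIZON + window)
    n_past_onsets = 0
    state = init
    tail: Trajectory | None = None

    while True:
        t_start = 0.0 if tail is None else float(tail.t[-1])
        part = integrate(p, state, window, t0=t_start)
        tail = part if tail is None else concatenate([tail, part])
        state = tail.state_at(-1)
        total_t = float(tail.t[-1])

        if tail.duration > keep:
            i0 = int(np.searchsorted(tail.t, total_t - keep))
            seg_full = segment(tail, threshold)
            n_past_onsets += int(np.sum(seg_full.onsets < tail.t[i0]))
            tail = tail.slice(i0, len(tail))

        seg = segment(tail, threshold)
        periods = np.diff(seg.onsets)
        if len(periods) >= 3:
            last3 = periods[-3:]
            rel = float((last3.max() - last3.min()) / last3.mean())
            if rel < PERIOD_RTOL:
                t_lo, t_hi = seg.onsets[-4], seg.onsets[-1]
                i0 = max(int(np.searchsorted(tail.t, t_lo)) - 1, 0)
                i1 = min(int(np.searchsorted(tail.t, t_hi)) + 1, len(tail))
                cycles = tail.slice(i0, i1)
                report = SettleReport(
                    converged=True, rhythm_lost=False,
                    n_discarded_cycles=n_past_onsets + len(seg.onsets) - 4,
                    period_rel_change=rel, final_state=state,
                )
                return cycles, report
        else:
            rel = float("nan")

        a_range = float(part.a.max() - part.a.min())
        lost_flat = a_range < FLATLINE_RANGE
        lost_quiet = False
        if total_t >= NO_EPISODE_HORIZON:
            recent = [ph for ph in seg.phases
                      if ph[0] == "AP" and ph[2] > total_t - NO_EPISODE_HORIZON]
            lost_quiet = len(recent) == 0
        if lost_flat or lost_quiet:
            report = SettleReport(
                converged=False, rhythm_lost=True,
                n_discarded_cycles=n_past_onsets + len(seg.onsets),
                period_rel_change=rel, final_state=state,
            )
            return tail, report

        if total_t >= SETTLE_CAP:
            raise ConvergenceError(
                f"no convergence or rhythm loss within {SETTLE_CAP} time units"
            )


def state_at_crossing(traj: Trajectory, kind: str = "onset", index: int = -1,
                      threshold: float = DEFAULT_THRESHOLD) -> State:
    """State at a threshold crossing, linearly interpolated between samples.

    ``kind`` selects upward ("onset") or downward ("offset") crossings of
    the activity; ``index`` picks which one (default: last).  The
    interpolated activity equals the threshold by construction.
    """
    seg = segment(traj, threshold)
    times = seg.onsets if kind == "onset" else seg.offsets
    if kind not in ("onset", "offset"):
        raise ValueError("kind must be 'onset' or 'offset'")
    if len(times) == 0:
        raise AnalysisError(f"trajectory contains no {kind} crossing")
    try:
        tc = times[index]
    except IndexError:
        raise AnalysisError(
            f"trajectory has only {len(times)} {kind} crossings"
        ) from None
    i = int(np.searchsorted(traj.t, tc, side="right")) - 1
    if i >= len(traj) - 1:
        i = len(traj) - 2
    frac = (tc - traj.t[i]) / (traj.t[i + 1] - traj.t[i])
    interp = lambda y: float(y[i] + frac * (y[i + 1] - y[i]))
    return State(a=interp(traj.a), s=interp(traj.s), theta=interp(traj.theta))


def first_crossing_time(p: ModelParams, init: State, direction: str,
                        t_max: float, threshold: float = DEFAULT_THRESHOLD,
                        chunk: float | None = None) -> float:
    """Time of the first threshold crossing of ``a`` when integrating from
    ``init``, excluding a crossing exactly at t = 0.

    ``direction`` is "down" (active phase termination) or "up" (silent
    phase termination).  Integration proceeds in chunks until the crossing
    is found.

    Raises
    ------
    DivergenceError
        If no crossing occurs within ``t_max``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if chunk is None:
        chunk = max(10.0 * max(p.tau_s, p.tau_theta), 500.0)
    state = init
    t0 = 0.0
    while t_max - t0 >= p.dt:
        part = integrate(p, state, min(chunk, t_max - t0), t0=t0)
        a, t = part.a, part.t
        # strict inequality on the leading sample keeps a start exactly on
        # the threshold (d = 0 at t = 0) from registering as a crossing
        d = a - threshold
        if direction == "down":
            idx = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
        else:
            idx = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0]
        if len(idx) > 0:
            i = idx[0]
            frac = (threshold - a[i]) / (a[i + 1] - a[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
        state = part.state_at(-1)
        t0 = float(part.t[-1])
    raise DivergenceError(
        f"no {direction}ward crossing within {t_max} time units"
    )
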