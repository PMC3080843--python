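"""Time-constant sensitivity measure of process contributions.

The central method: the contribution of a slow process to a phase of the
oscillation is quantified by the normalized acute sensitivity of that
phase's duration to the process's time constant,

    C^s_AP = (dAP/AP) / (dtau_s/tau_s),      and analogously for
    C^s_SP, C^theta_AP, C^theta_SP.

The perturbation is applied at the start of the phase (the limit-cycle
state at the phase-onset crossing is the initial condition) and only the
acute effect is measured — the system is not allowed to re-equilibrate.
Each coefficient lies in [0, 1]: 0 means the process does not shape the
phase, 1 means it alone does.  Because phase durations are homogeneous of
degree one in (tau_s, tau_theta) — scaling both time constants scales the
whole cycle — Euler's theorem gives the summation relation

    C^s_xP + C^theta_xP = 1        (x in {A, S})

on any cycle where both slow variables vary monotonically within each
phase.  The pair for a phase is condensed into a single index

    C_xP = (C^s_xP - C^theta_xP) / (C^s_xP + C^theta_xP)  in [-1, 1],

+1 meaning the divisive process (s) alone controls the phase, -1 the
subtractive one (theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .correlative import CorrelativeResult, correlative
from .episodes import DEFAULT_THRESHOLD, CycleMetrics, metrics, segment
from .exceptions import MeasureUndefinedError, ProtocolError
from .params import ModelParams, State
from .simulate import first_crossing_time, settle, state_at_crossing
from .trajectory import Trajectory

__all__ = ["ContributionSet", "CombinedMeasures", "SweepTable",
           "perturbed_phase", "contributions", "combine", "sweep",
           "DEFAULT_DELTA_FRAC", "SWEEP_AXES"]

#: Default fractional time-constant perturbation (4%): small enough for the
#: linear-response regime, large enough for a measurable duration change.
DEFAULT_DELTA_FRAC = 0.04

SWEEP_AXES = ("tau_ratio", "w", "theta0", "g")


@dataclass(frozen=True)
class ContributionSet:
    """The four normalized sensitivities and their per-phase sums.

    ``monotone_warning`` is set when a slow variable fails to vary
    monotonically within a phase of the unperturbed cycle — the condition
    under which the summation relation is guaranteed.
    """

    Cs_AP: float
    Cs_SP: float
    Ctheta_AP: float
    Ctheta_SP: float
    delta_frac: float
    monotone_warning: bool = False

    @property
    def sum_AP(self) -> float:
        return self.Cs_AP + self.Ctheta_AP

    @property
    def sum_SP(self) -> float:
        return self.Cs_SP + self.Ctheta_SP


@dataclass(frozen=True)
class CombinedMeasures:
    """Normalized-difference indices, one per phase, in [-1, 1]."""

    C_AP: float
    C_SP: float


@dataclass
class _Baseline:
    """Converged-cycle quantities needed by the perturbation runs."""

    traj: Trajectory
    AP: float
    SP: float
    onset_state: State
    offset_state: State
    monotone_ok: bool


def _baseline(p: ModelParams, threshold: float) -> _Baseline:
    traj, report = settle(p, threshold=threshold)
    if not report.converged:
        raise ProtocolError("system is not rhythmic at these parameters")
    seg = segment(traj, threshold)
    ap_phase = [ph for ph in seg.phases if ph[0] == "AP"][-1]
    sp_phase = [ph for ph in seg.phases if ph[0] == "SP"][-1]
    onset_idx = int(np.argmin(np.abs(seg.onsets - ap_phase[1])))
    offset_idx = int(np.argmin(np.abs(seg.offsets - sp_phase[1])))
    return _Baseline(
        traj=traj,
        AP=ap_phase[2] - ap_phase[1],
        SP=sp_phase[2] - sp_phase[1],
        onset_state=state_at_crossing(traj, "onset", onset_idx, threshold),
        offset_state=state_at_crossing(traj, "offset", offset_idx, threshold),
        monotone_ok=_phases_monotone(traj, seg.phases[-2:]),
    )


def _phases_monotone(traj: Trajectory, phases, frac_tol: float = 0.05) -> bool:
    """Whether s and theta each vary monotonically within each phase.

    The slow variables turn around slightly *after* the threshold crossing
    that bounds a phase (the crossing sits inside the fast jump), so a
    strict sample-by-sample check would always fail.  Instead a variable
    counts as monotone when its retracement — the largest move against its
    net direction over the phase — is below ``frac_tol`` of its excursion.
    """
    for _, t0, t1 in phases:
        mask = (traj.t > t0) & (traj.t < t1)
        for y in (traj.s[mask], traj.theta[mask]):
            if len(y) < 3:
                continue
            rng = float(y.max() - y.min())
            if rng < 1e-6:
                continue
            net = y[-1] - y[0]
            if net >= 0:
                retrace = float(np.max(np.maximum.accumulate(y) - y))
            else:
                retrace = float(np.max(y - np.minimum.accumulate(y)))
            if retrace > frac_tol * rng:
                return False
    return True


def _measure_phase(p: ModelParams, base: _Baseline, which_tau: str,
                   phase: str, delta_frac: float, threshold: float) -> float:
    if which_tau == "s":
        p_run = p.replace(tau_s=p.tau_s * (1.0 + delta_frac))
    elif which_tau == "theta":
        p_run = p.replace(tau_theta=p.tau_theta * (1.0 + delta_frac))
    else:
        raise ValueError("which_tau must be 's' or 'theta'")
    period = base.AP + base.SP
    if phase == "AP":
        init, direction = base.onset_state, "down"
    elif phase == "SP":
        init, direction = base.offset_state, "up"
    else:
        raise ValueError("phase must be 'AP' or 'SP'")
    return first_crossing_time(
        p_run, init, direction, t_max=50.0 * period, threshold=threshold,
        chunk=max(2.0 * period, 100.0),
    )


def perturbed_phase(p: ModelParams, which_tau: str, phase: str,
                    delta_frac: float,
                    threshold: float = DEFAULT_THRESHOLD) -> float:
    """Duration of one phase after an acute fractional perturbation of a
    slow time constant.

    The run starts from the limit-cycle state at the phase's onset
    crossing, with the selected time constant multiplied by
    ``(1 + delta_frac)`` for the whole run, and ends at the
    phase-terminating crossing.  A ``delta_frac = 0`` run reproduces the
    unperturbed duration.
    """
    base = _baseline(p, threshold)
    return _measure_phase(p, base, which_tau, phase, delta_frac, threshold)


def contributions(p: ModelParams, delta_frac: float = DEFAULT_DELTA_FRAC,
                  threshold: float = DEFAULT_THRESHOLD) -> ContributionSet:
    """All four sensitivity coefficients via the acute 4% protocol.

    Baseline durations come from the same converged cycle whose crossing
    states seed the perturbed runs, so settling bias cancels.
    """
    if delta_frac <= 0:
        raise ValueError("delta_frac must be > 0")
    base = _baseline(p, threshold)
    durations = {
        (wt, ph): _measure_phase(p, base, wt, ph, delta_frac, threshold)
        for wt in ("s", "theta") for ph in ("AP", "SP")
    }

    def coeff(wt: str, ph: str) -> float:
        ref = base.AP if ph == "AP" else base.SP
        return ((durations[(wt, ph)] - ref) / ref) / delta_frac

    return ContributionSet(
        Cs_AP=coeff("s", "AP"), Cs_SP=coeff("s", "SP"),
        Ctheta_AP=coeff("theta", "AP"), Ctheta_SP=coeff("theta", "SP"),
        delta_frac=delta_frac, monotone_warning=not base.monotone_ok,
    )


def combine(cs: ContributionSet) -> CombinedMeasures:
    """Condense the per-process coefficients into one index per phase."""
    out = []
    for cs_x, ct_x, name in ((cs.Cs_AP, cs.Ctheta_AP, "AP"),
                             (cs.Cs_SP, cs.Ctheta_SP, "SP")):
        den = cs_x + ct_x
        if abs(den) < 1e-9:
            raise MeasureUndefinedError(
                f"combined measure undefined for {name}: both coefficients ~ 0"
            )
        out.append((cs_x - ct_x) / den)
    return CombinedMeasures(C_AP=out[0], C_SP=out[1])


@dataclass(frozen=True)
class SweepRow:
    """One sweep point: full parameter set plus every measure computed on it."""

    axis_value: float
    params: ModelParams
    rhythmic: bool
    cycle: CycleMetrics | None = None
    contrib: ContributionSet | None = None
    combined: CombinedMeasures | None = None
    corr: CorrelativeResult | None = None


@dataclass(frozen=True)
class SweepTable:
    axis: str
    rows: list[SweepRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec: dict = {self.axis: row.axis_value, "rhythmic": row.rhythmic}
            rec.update(row.params.to_dict())
            nan = float("nan")
            cm = row.cycle
            rec.update(AP=cm.AP if cm else nan, SP=cm.SP if cm else nan,
                       period=cm.period if cm else nan,
                       duty=cm.duty if cm else nan)
            cs = row.contrib
            rec.update(
                Cs_AP=cs.Cs_AP if cs else nan, Cs_SP=cs.Cs_SP if cs else nan,
                Ctheta_AP=cs.Ctheta_AP if cs else nan,
                Ctheta_SP=cs.Ctheta_SP if cs else nan,
                sum_AP=cs.sum_AP if cs else nan,
                sum_SP=cs.sum_SP if cs else nan,
            )
            cb = row.combined
            rec.update(C_AP=cb.C_AP if cb else nan, C_SP=cb.C_SP if cb else nan)
            co = row.corr
            rec.update(corr_C=co.C if co else nan, corr_c=co.c if co else nan)
            recs.append(rec)
        return pd.DataFrame(recs)


def _apply_axis(base: ModelParams, axis: str, value: float) -> ModelParams:
    if axis == "tau_ratio":
        # ratio = tau_theta/tau_s varied through tau_s, with tau_theta held
        # fixed: the slower process then never drops below the base value,
        # keeping every sweep point in the relaxation regime
        return base.replace(tau_s=base.tau_theta / value)
    if axis in ("w", "theta0", "g"):
        return base.replace(**{axis: value})
    raise ValueError(f"axis must be one of {SWEEP_AXES}")


def sweep(base: ModelParams, axis: str, values: Sequence[float],
          delta_frac: float = DEFAULT_DELTA_FRAC,
          threshold: float = DEFAULT_THRESHOLD) -> SweepTable:
    """Compute every measure across a one-parameter sweep.

    ``tau_ratio`` varies ``tau_s`` with ``tau_theta`` held fixed.  Each row
    is computed independently; non-rhythmic rows are flagged and retained
    with the measures left empty.
    """
    rows = []
    for value in values:
        p = _apply_axis(base, axis, value)
        try:
            traj, report = settle(p, threshold=threshold)
        except Exception:
            report = None
        if report is None or not report.converged:
            rows.append(SweepRow(axis_value=value, params=p, rhythmic=False))
            continue
        cm = metrics(segment(traj, threshold))
        cs = contributions(p, delta_frac=delta_frac, threshold=threshold)
        cb = combine(cs)
        try:
            co = correlative(traj, p, threshold)
        except MeasureUndefinedError:
            co = None
        rows.append(SweepRow(axis_value=value, params=p, rhythmic=True,
                             cycle=cm, contrib=cs, combined=cb, corr=co))
    return SweepTable(axis=axis, rows=rows)
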