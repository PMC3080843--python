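"""Phase-plane (geometric) estimate of the process contributions.

During the silent phase the trajectory in the (a, s) plane drifts right
(s recovers) while the dynamic a-nullcline's low knee drifts left (theta
recovers); the phase ends when trajectory and knee meet.  Comparing the
two speeds, with ds ~ dtheta * (tau_theta/tau_s) for the trajectory and
ds_k ~ (g/w) * dtheta / a_k for the knee, gives the rescaled ratio

    ds/ds_k = (tau_theta/tau_s) * (w/g) * a_k

where a_k is the knee activity at the transition.  Identifying ds/ds_k
with the ratio of the two sensitivity coefficients yields the geometric
combined index

    C_geo = (ds/ds_k - 1) / (ds/ds_k + 1)

per phase (high knee at episode termination for the active phase, low
knee at episode onset for the silent phase).  The derivation assumes both
slow variables move at nearly uniform speed within a phase; when theta
saturates near its asymptote (large theta0 with tau_theta << tau_s) that
assumption fails and the geometric and sensitivity measures genuinely
disagree — the comparison report flags, but never corrects, such cases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contributions import (DEFAULT_DELTA_FRAC, CombinedMeasures,
                            ContributionSet, combine, contributions)
from .episodes import DEFAULT_THRESHOLD, segment
from .exceptions import GeometricInapplicableError, ProtocolError
from .model import find_knees
from .params import ModelParams
from .simulate import settle, state_at_crossing

__all__ = ["GeometricResult", "MeasureComparison", "geometric",
           "compare_measures", "AGREEMENT_BAND"]

#: |sensitivity - geometric| above this flags a discrepant regime.
AGREEMENT_BAND = 0.15


@dataclass(frozen=True)
class GeometricResult:
    """Knee-based contribution estimate at the cycle's transitions.

    ``ratio_AP``/``ratio_SP`` are the rescaled ratios ds/ds_k =
    (tau_theta/tau_s)*(w/g)*a_k evaluated with the high-knee activity at
    episode termination and the low-knee activity at episode onset.
    """

    theta_at_onset: float
    theta_at_termination: float
    a_k_AP: float
    a_k_SP: float
    ratio_AP: float
    ratio_SP: float
    C_geo_AP: float
    C_geo_SP: float


@dataclass(frozen=True)
class MeasureComparison:
    """Side-by-side sensitivity vs geometric contribution indices."""

    sensitivity: CombinedMeasures
    geometric: GeometricResult
    contrib: ContributionSet
    diff_AP: float
    diff_SP: float
    discrepant: bool


def geometric(p: ModelParams,
              threshold: float = DEFAULT_THRESHOLD) -> GeometricResult:
    """Evaluate the phase-plane estimate on the converged limit cycle.

    theta is read at the interpolated threshold crossings of the settled
    cycle; the knees are located at those theta values.

    Raises
    ------
    GeometricInapplicableError
        When g = 0 (the knee drift ratio is undefined) or no knee exists
        at a transition theta.
    """
    if p.g == 0:
        raise GeometricInapplicableError(
            "geometric measure undefined for g = 0: theta does not move"
        )
    traj, report = settle(p, threshold=threshold)
    if not report.converged:
        raise ProtocolError("system is not rhythmic at these parameters")
    theta_on = state_at_crossing(traj, "onset", -1, threshold).theta
    theta_off = state_at_crossing(traj, "offset", -1, threshold).theta

    knees_on = find_knees(theta_on, p)
    knees_off = find_knees(theta_off, p)
    if not knees_on.exists:
        raise GeometricInapplicableError(
            f"no knees at episode-onset theta = {theta_on:.4f}"
        )
    if not knees_off.exists:
        raise GeometricInapplicableError(
            f"no knees at episode-termination theta = {theta_off:.4f}"
        )
    a_k_SP = knees_on.a_LK     # low knee governs silent-phase termination
    a_k_AP = knees_off.a_HK    # high knee governs active-phase termination
    prefactor = (p.tau_theta / p.tau_s) * (p.w / p.g)
    ratio_AP = prefactor * a_k_AP
    ratio_SP = prefactor * a_k_SP
    return GeometricResult(
        theta_at_onset=theta_on, theta_at_termination=theta_off,
        a_k_AP=a_k_AP, a_k_SP=a_k_SP,
        ratio_AP=ratio_AP, ratio_SP=ratio_SP,
        C_geo_AP=(ratio_AP - 1.0) / (ratio_AP + 1.0),
        C_geo_SP=(ratio_SP - 1.0) / (ratio_SP + 1.0),
    )


def compare_measures(p: ModelParams,
                     delta_frac: float = DEFAULT_DELTA_FRAC,
                     threshold: float = DEFAULT_THRESHOLD) -> MeasureComparison:
    """Compute both the sensitivity and geometric indices and their gap.

    ``discrepant`` flags any per-phase gap above 0.15 — expected in the
    regime where theta saturates during the silent phase (large theta0,
    tau_theta much smaller than tau_s); agreement is not asserted there.
    """
    cs = contributions(p, delta_frac=delta_frac, threshold=threshold)
    cb = combine(cs)
    geo = geometric(p, threshold=threshold)
    diff_ap = cb.C_AP - geo.C_geo_AP
    diff_sp = cb.C_SP - geo.C_geo_SP
    return MeasureComparison(
        sensitivity=cb, geometric=geo, contrib=cs,
        diff_AP=diff_ap, diff_SP=diff_sp,
        discrepant=max(abs(diff_ap), abs(diff_sp)) > AGREEMENT_BAND,
    )
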