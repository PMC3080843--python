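"""Correlative (passive-observation) measure of process contributions.

The idea mimics what an experimenter could extract from recordings alone:
the process whose weighted excursion is larger over a cycle is deemed the
larger contributor.  With Delta_s and Delta_theta the per-cycle ranges of
the two slow variables, the weighted ratio is

    R = (w * Delta_s) / (g * Delta_theta)

and the index

    C = (R - 1) / (R + 1)   in (-1, 1).

Because an exponentially relaxing process covers a range inversely
proportional to its time constant, R is approximated analytically by
r = (w/g) * (tau_theta/tau_s), giving the closed-form curve
c = (r - 1)/(r + 1) against which the simulated C is compared.

C near +1 reads as "depression (s) dominates", near -1 as "adaptation
(theta) dominates".  Both processes cover the same range during the active
and silent phase, so this measure cannot distinguish episode initiation
from termination — one of its key limitations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .episodes import DEFAULT_THRESHOLD, segment
from .exceptions import AnalysisError, MeasureUndefinedError
from .params import ModelParams
from .trajectory import Trajectory

__all__ = ["CorrelativeResult", "correlative"]


@dataclass(frozen=True)
class CorrelativeResult:
    """Ranges, weighted ratio and index, with their analytic counterparts."""

    delta_s: float
    delta_theta: float
    R: float
    C: float
    r: float
    c: float


def correlative(traj: Trajectory, p: ModelParams,
                threshold: float = DEFAULT_THRESHOLD) -> CorrelativeResult:
    """Correlative index measured on a converged limit-cycle trajectory.

    Ranges are taken as max - min over an integer number of cycles
    (onset to onset).  Undefined when g = 0 (the adaptation excursion
    carries zero weight), which is signalled explicitly.
    """
    if p.g == 0:
        raise MeasureUndefinedError(
            "correlative measure undefined for g = 0 (no weighted theta range)"
        )
    seg = segment(traj, threshold)
    if len(seg.onsets) < 2:
        raise AnalysisError(
            "correlative measure needs at least one full onset-to-onset cycle"
        )
    mask = (traj.t >= seg.onsets[0]) & (traj.t <= seg.onsets[-1])
    s, theta = traj.s[mask], traj.theta[mask]
    delta_s = float(s.max() - s.min())
    delta_theta = float(theta.max() - theta.min())
    R = (p.w * delta_s) / (p.g * delta_theta)
    r = (p.w / p.g) * (p.tau_theta / p.tau_s)
    return CorrelativeResult(
        delta_s=delta_s, delta_theta=delta_theta,
        R=R, C=(R - 1.0) / (R + 1.0),
        r=r, c=(r - 1.0) / (r + 1.0),
    )
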