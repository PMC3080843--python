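"""Threshold segmentation of trajectories into active and silent phases.

An active phase (AP, an "episode") is the interval where the activity ``a``
exceeds a fixed threshold, 0.35 by default; the sub-threshold interval
between episodes is the silent phase (SP).  Crossing times are linearly
interpolated between the bracketing samples.  No hysteresis is applied:
the relaxation dynamics cross the threshold cleanly at the fixed step
used here, so a single threshold suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AnalysisError
from .trajectory import Trajectory

DEFAULT_THRESHOLD = 0.35

__all__ = ["DEFAULT_THRESHOLD", "EpisodeSegmentation", "CycleMetrics",
           "segment", "metrics"]


@dataclass(frozen=True)
class EpisodeSegmentation:
    """Interpolated phase boundaries of a trajectory.

    ``onsets`` are upward threshold crossings (episode starts), ``offsets``
    downward crossings (episode ends); they strictly alternate.  ``phases``
    lists only the complete phases — intervals bounded by two crossings —
    as ``(label, t_start, t_end)`` with label ``"AP"`` or ``"SP"``.
    """

    threshold: float
    onsets: np.ndarray
    offsets: np.ndarray
    phases: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def ap_durations(self) -> np.ndarray:
        return np.array([t1 - t0 for lbl, t0, t1 in self.phases if lbl == "AP"])

    @property
    def sp_durations(self) -> np.ndarray:
        return np.array([t1 - t0 for lbl, t0, t1 in self.phases if lbl == "SP"])

    @property
    def n_complete_cycles(self) -> int:
        return min(len(self.ap_durations), len(self.sp_durations))


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle durations averaged over all complete cycles retained.

    ``period = AP + SP`` exactly and ``duty = AP / (AP + SP)``.
    """

    AP: float
    SP: float
    period: float
    duty: float
    n_cycles_averaged: int


def _crossings(t: np.ndarray, a: np.ndarray, threshold: float):
    """Interpolated upward and downward crossing times of ``a``.

    A sample exactly on the threshold is attributed to the interval ending
    there (interpolation then lands the crossing on the grid point).
    """
    d = a - threshold
    up = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0]
    down = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]

    def interp(idx):
        if len(idx) == 0:
            return np.empty(0)
        frac = (threshold - a[idx]) / (a[idx + 1] - a[idx])
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return interp(up), interp(down)


def segment(traj: Trajectory, threshold: float = DEFAULT_THRESHOLD) -> EpisodeSegmentation:
    """Segment a trajectory into active and silent phases.

    Zero crossings yield an empty segmentation (not an error).
    """
    if len(traj) == 0:
        raise AnalysisError("cannot segment an empty trajectory")
    onsets, offsets = _crossings(traj.t, traj.a, threshold)

    events = sorted(
        [(t, "onset") for t in onsets] + [(t, "offset") for t in offsets]
    )
    phases: list[tuple[str, float, float]] = []
    for (t0, k0), (t1, k1) in zip(events, events[1:]):
        if k0 == "onset" and k1 == "offset":
            phases.append(("AP", t0, t1))
        elif k0 == "offset" and k1 == "onset":
            phases.append(("SP", t0, t1))
    return EpisodeSegmentation(
        threshold=threshold, onsets=onsets, offsets=offsets, phases=phases
    )


def metrics(seg: EpisodeSegmentation) -> CycleMetrics:
    """Average AP/SP durations, period and duty cycle of a segmentation.

    Requires at least one complete active and one complete silent phase.
    """
    aps, sps = seg.ap_durations, seg.sp_durations
    if len(aps) == 0 or len(sps) == 0:
        raise AnalysisError(
            "metrics require at least one complete active and silent phase"
        )
    ap, sp = float(np.mean(aps)), float(np.mean(sps))
    return CycleMetrics(
        AP=ap, SP=sp, period=ap + sp, duty=ap / (ap + sp),
        n_cycles_averaged=min(len(aps), len(sps)),
    )
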