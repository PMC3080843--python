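"""Blockade protocol: delete the adaptation process (g -> 0) mid-run.

Mimics a pharmacological block / knockout experiment: after the control
rhythm has settled, g is set to 0 at an episode onset and the effect on
active- and silent-phase durations is measured both acutely (the first
complete phases after the block) and after the blocked system has
re-settled.  With sufficient cell excitability (low theta0) depression
alone cannot silence the network and rhythmicity is lost outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from .episodes import DEFAULT_THRESHOLD, CycleMetrics, metrics, segment
from .exceptions import DivergenceError, ProtocolError
from .params import ModelParams, State
from .simulate import first_crossing_time, integrate, settle, state_at_crossing

__all__ = ["BlockadeResult", "blockade"]


@dataclass(frozen=True)
class BlockadeResult:
    """Outcome of a theta-block experiment.

    ``transient_AP``/``transient_SP`` are the first complete phase
    durations right after the block; ``equilibrated`` is absent whenever
    ``rhythm_lost`` is set.  Percent changes follow the
    100 * (blocked - control)/control convention.
    """

    control: CycleMetrics
    transient_AP: float | None
    transient_SP: float | None
    equilibrated: CycleMetrics | None
    rhythm_lost: bool
    pct_change_AP: float | None = None
    pct_change_SP: float | None = None


def blockade(p: ModelParams, threshold: float = DEFAULT_THRESHOLD,
             require_control_rhythm: bool = True) -> BlockadeResult:
    """Block the adaptation process and report acute and settled effects.

    The block (g = 0) is applied at an episode onset of the settled
    control rhythm, so the transient AP is well defined.
    """
    control_traj, control_report = settle(p, threshold=threshold)
    if not control_report.converged:
        if require_control_rhythm:
            raise ProtocolError("control parameters do not yield a rhythm")
        raise ProtocolError("control settling failed")
    control = metrics(segment(control_traj, threshold))
    onset_state = state_at_crossing(control_traj, "onset", -1, threshold)

    p_block = p.replace(g=0.0)
    t_cap = 50.0 * control.period
    transient_AP = transient_SP = None
    post_state: State = onset_state
    try:
        transient_AP = first_crossing_time(
            p_block, onset_state, "down", t_cap, threshold,
            chunk=max(2.0 * control.period, 100.0),
        )
        run = integrate(p_block, onset_state,
                        duration=transient_AP + control.period * 2, )
        offset_state = state_at_crossing(run, "offset", 0, threshold)
        transient_SP = first_crossing_time(
            p_block, offset_state, "up", t_cap, threshold,
            chunk=max(2.0 * control.period, 100.0),
        )
        post_state = offset_state
    except DivergenceError:
        # activity never comes back down (or up): rhythm abolished acutely
        return BlockadeResult(
            control=control, transient_AP=transient_AP,
            transient_SP=transient_SP, equilibrated=None, rhythm_lost=True,
        )

    blocked_traj, blocked_report = settle(p_block, post_state, threshold)
    if blocked_report.rhythm_lost or not blocked_report.converged:
        return BlockadeResult(
            control=control, transient_AP=transient_AP,
            transient_SP=transient_SP, equilibrated=None, rhythm_lost=True,
        )
    equilibrated = metrics(segment(blocked_traj, threshold))
    return BlockadeResult(
        control=control, transient_AP=transient_AP,
        transient_SP=transient_SP, equilibrated=equilibrated,
        rhythm_lost=False,
        pct_change_AP=100.0 * (equilibrated.AP - control.AP) / control.AP,
        pct_change_SP=100.0 * (equilibrated.SP - control.SP) / control.SP,
    )
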