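"""Preset scenario library: the standard sweep tables.

Each preset regenerates one of the package's reference tables from
scratch.  Parameter grids whose exact published values are shown only
graphically (``fig6`` theta0 levels, ``fig7`` base excitability, the
blockade grid) are representative defaults, not canonical reproductions;
they are chosen inside the documented sweep ranges.
"""

from __future__ import annotations

import pandas as pd

from .blockade import blockade
from .contributions import contributions, combine, sweep
from .correlative import correlative
from .episodes import metrics, segment
from .exceptions import ProtocolError, RhythmError
from .geometry import compare_measures
from .params import ModelParams
from .simulate import settle

__all__ = ["PRESETS", "run_preset", "blockade_grid"]

_RATIOS = (0.1, 0.3, 1.0, 3.0, 10.0)


def _ratio_params(base: ModelParams, ratio: float) -> ModelParams:
    # ratio = tau_theta/tau_s varied through tau_s, tau_theta fixed
    return base.replace(tau_s=base.tau_theta / ratio)


def fig1c(base: ModelParams) -> pd.DataFrame:
    """Correlative index C vs tau_theta/tau_s at two excitability levels,
    with the analytic curve c = (r-1)/(r+1)."""
    rows = []
    for theta0 in (0.0, 0.18):
        for ratio in _RATIOS:
            p = _ratio_params(base.replace(theta0=theta0), ratio)
            traj, report = settle(p)
            if not report.converged:
                rows.append({"tau_ratio": ratio, "theta0": theta0,
                             "rhythmic": False})
                continue
            res = correlative(traj, p)
            rows.append({"tau_ratio": ratio, "theta0": theta0,
                         "rhythmic": True, "C": res.C, "c": res.c,
                         "delta_s": res.delta_s,
                         "delta_theta": res.delta_theta})
    return pd.DataFrame(rows)


def fig3(base: ModelParams) -> pd.DataFrame:
    """AP, SP and duty cycle as tau_s, tau_theta, or both are varied."""
    taus = (25.0, 75.0, 250.0, 750.0, 2500.0)
    rows = []
    for mode in ("tau_s", "tau_theta", "both"):
        for tau in taus:
            if mode == "tau_s":
                p = base.replace(tau_s=tau)
            elif mode == "tau_theta":
                p = base.replace(tau_theta=tau)
            else:
                p = base.replace(tau_s=tau, tau_theta=tau)
            traj, report = settle(p)
            row = {"varied": mode, "tau": tau, "rhythmic": report.converged}
            if report.converged:
                m = metrics(segment(traj))
                row.update(AP=m.AP, SP=m.SP, period=m.period, duty=m.duty)
            rows.append(row)
    return pd.DataFrame(rows)


def fig5(base: ModelParams) -> pd.DataFrame:
    """Sensitivity coefficients, their sums and the combined indices
    across the tau_theta/tau_s ratio sweep."""
    return sweep(base, "tau_ratio", _RATIOS).to_dataframe()


def fig6(base: ModelParams) -> pd.DataFrame:
    """C_AP and C_SP vs connectivity w at three excitability levels."""
    frames = []
    for theta0 in (0.0, 0.09, 0.18):
        df = sweep(base.replace(theta0=theta0), "w",
                   (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)).to_dataframe()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fig7(base: ModelParams) -> pd.DataFrame:
    """C_AP and C_SP vs adaptation strength g (moderate excitability so
    the rhythm survives the g -> 0 limit)."""
    return sweep(base.replace(theta0=0.12), "g",
                 (0.05, 0.1, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5)).to_dataframe()


def fig8b(base: ModelParams) -> pd.DataFrame:
    """Sensitivity vs geometric combined indices across a w sweep."""
    rows = []
    for w in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0):
        p = base.replace(w=w)
        row: dict = {"w": w}
        try:
            comp = compare_measures(p)
        except RhythmError as exc:
            row.update(rhythmic=False, note=type(exc).__name__)
        else:
            row.update(
                rhythmic=True,
                C_AP=comp.sensitivity.C_AP, C_SP=comp.sensitivity.C_SP,
                C_geo_AP=comp.geometric.C_geo_AP,
                C_geo_SP=comp.geometric.C_geo_SP,
                diff_AP=comp.diff_AP, diff_SP=comp.diff_SP,
                discrepant=comp.discrepant,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def blockade_grid(base: ModelParams,
                  theta0_values=(0.06, 0.12, 0.18),
                  ratio_values=(0.5, 1.0, 2.0)) -> pd.DataFrame:
    """Blockade outcomes over a theta0 x (tau_theta/tau_s) grid.

    A representative 3x3 layout (ratio varied through tau_theta here,
    so the control stays at tau_s = 250); not a canonical reproduction
    of any published case grid.
    """
    rows = []
    case = 0
    for theta0 in theta0_values:
        for ratio in ratio_values:
            case += 1
            p = base.replace(theta0=theta0, tau_theta=base.tau_s * ratio)
            row = {"case": case, "theta0": theta0, "tau_ratio": ratio}
            try:
                res = blockade(p)
            except ProtocolError:
                row.update(control_rhythmic=False, rhythm_lost=True)
            else:
                row.update(
                    control_rhythmic=True, rhythm_lost=res.rhythm_lost,
                    control_AP=res.control.AP, control_SP=res.control.SP,
                    pct_change_AP=res.pct_change_AP,
                    pct_change_SP=res.pct_change_SP,
                )
            rows.append(row)
    return pd.DataFrame(rows)


PRESETS = {
    "fig1c": fig1c,
    "fig3": fig3,
    "fig5": fig5,
    "fig6": fig6,
    "fig7": fig7,
    "fig8b": fig8b,
}


def run_preset(name: str, base: ModelParams | None = None) -> pd.DataFrame:
    """Regenerate a preset sweep table from scratch."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](base if base is not None else ModelParams())
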