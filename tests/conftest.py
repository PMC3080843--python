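"""Shared fixtures: default-parameter limit cycle and measures.

The expensive settle/perturbation runs at default parameters are computed
once per session and shared; tests that need other parameter sets compute
their own.
"""

import numpy as np
import pytest

from rhythmcontrib import (ModelParams, contributions, combine, segment,
                           settle)
from rhythmcontrib.trajectory import Trajectory


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def settled_default(default_params):
    """Converged limit cycle at Table-1 default parameters."""
    traj, report = settle(default_params)
    assert report.converged
    return traj, report


@pytest.fixture(scope="session")
def default_contribs(default_params):
    return contributions(default_params)


@pytest.fixture(scope="session")
def default_combined(default_contribs):
    return combine(default_contribs)


def make_square_wave(high=0.6, low=0.1, t_high=100.0, t_low=300.0,
                     n_cycles=4, dt=0.5):
    """Synthetic square-wave trajectory with instantaneous jumps between
    adjacent samples.  The default levels are symmetric about the 0.35
    threshold, so interpolated crossings land exactly mid-jump and the
    constructed durations are preserved exactly."""
    period = t_high + t_low
    t = np.arange(0.0, n_cycles * period + dt / 2, dt)
    phase = np.mod(t, period)
    a = np.where(phase < t_high, high, low)
    z = np.zeros_like(t)
    return Trajectory(t=t, a=a, s=z + 0.5, theta=z + 0.5, dt=dt)


def make_triangle_wave(peak=0.9, trough=0.1, half=50.0, n_cycles=4, dt=0.05):
    """Symmetric triangle wave with known slopes, for analytic crossings."""
    period = 2 * half
    t = np.arange(0.0, n_cycles * period + dt / 2, dt)
    phase = np.mod(t, period)
    up = phase < half
    a = np.where(up, trough + (peak - trough) * phase / half,
                 peak - (peak - trough) * (phase - half) / half)
    z = np.zeros_like(t)
    return Trajectory(t=t, a=a, s=z + 0.5, theta=z + 0.5, dt=dt)
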