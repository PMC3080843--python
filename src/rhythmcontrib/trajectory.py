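"""Trajectory container: uniformly sampled (t, a, s, theta) paths."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import State


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled solution path.

    ``t`` is a strictly increasing uniform time grid (units of ``tau_a``);
    ``a``, ``s``, ``theta`` are the aligned state samples, all in [0, 1].
    ``dt`` is the step actually used.
    """

    t: np.ndarray
    a: np.ndarray
    s: np.ndarray
    theta: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.a) == len(self.s) == len(self.theta) == n):
            raise ValueError("trajectory columns must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def state_at(self, i: int) -> State:
        return State(a=float(self.a[i]), s=float(self.s[i]), theta=float(self.theta[i]))

    def slice(self, i0: int, i1: int) -> "Trajectory":
        """Sub-trajectory over sample indices [i0, i1)."""
        return Trajectory(
            t=self.t[i0:i1], a=self.a[i0:i1], s=self.s[i0:i1],
            theta=self.theta[i0:i1], dt=self.dt,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "a": self.a, "s": self.s, "theta": self.theta}
        )

    def to_csv(self, path) -> None:
        """Write as CSV with columns t,a,s,theta."""
        self.to_dataframe().to_csv(path, index=False)

    def to_parquet(self, path) -> None:
        """Binary columnar export for large sweeps."""
        self.to_dataframe().to_parquet(path, index=False)


def concatenate(parts: list[Trajectory]) -> Trajectory:
    """Join contiguous trajectory pieces, dropping duplicated junction samples.

    Each part is expected to start at the sample where the previous one
    ended (as produced by chained ``integrate`` calls).
    """
    if not parts:
        raise ValueError("no trajectory parts to concatenate")
    ts, as_, ss, ths = [parts[0].t], [parts[0].a], [parts[0].s], [parts[0].theta]
    for prev, part in zip(parts, parts[1:]):
        off = 1 if np.isclose(part.t[0], prev.t[-1]) else 0
        ts.append(part.t[off:])
        as_.append(part.a[off:])
        ss.append(part.s[off:])
        ths.append(part.theta[off:])
    return Trajectory(
        t=np.concatenate(ts), a=np.concatenate(as_), s=np.concatenate(ss),
        theta=np.concatenate(ths), dt=parts[0].dt,
    )
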