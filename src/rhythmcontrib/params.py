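"""Model parameters and state for the excitatory-network relaxation oscillator.

The model describes the mean activity ``a`` of an excitatory neural
population subject to two slow negative feedback processes: synaptic
depression ``s`` (divisive — it scales the recurrent input ``w*s*a``) and
cellular adaptation ``theta`` (subtractive — it raises the effective firing
threshold by ``g*theta``).  Time is measured in units of the activity time
constant ``tau_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Iterator, Mapping

from .exceptions import ParameterError


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the mean-field model.

    Defaults are the typical values used throughout; bracketed sweep ranges
    quoted in the field comments are documented exploration ranges, not hard
    limits.

    Attributes
    ----------
    w : float
        Network connectivity (synaptic strength); sweep range 0.5-3.5.
    theta0 : float
        Input for half-maximal activation (baseline cell threshold);
        sweep range -0.2-0.2.
    k_a : float
        Spread of the activity sigmoid ``a_inf``.
    theta_s : float
        Activity at half-maximal depression.
    k_s : float
        Spread of the depression sigmoid ``s_inf``.
    tau_s : float
        Time constant of synaptic depression, in units of ``tau_a``;
        sweep range 25-2500.
    theta_theta : float
        Activity at half-maximal adaptation.
    k_theta : float
        Spread of the adaptation sigmoid ``theta_inf``.
    tau_theta : float
        Time constant of cellular adaptation; sweep range 25-2500.
    g : float
        Strength ("conductance") of the adaptation process; sweep range
        0-1.5.  ``g = 0`` removes adaptation entirely.
    tau_a : float
        Activity time constant; fixed at 1 (it defines the time unit).
    dt : float
        Fixed integrator step.
    """

    w: float = 1.0
    theta0: float = 0.0
    k_a: float = 0.05
    theta_s: float = 0.3
    k_s: float = 0.05
    tau_s: float = 250.0
    theta_theta: float = 0.3
    k_theta: float = 0.05
    tau_theta: float = 250.0
    g: float = 1.0
    tau_a: float = 1.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        for name in ("tau_s", "tau_theta", "tau_a"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("k_a", "k_s", "k_theta"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.g < 0:
            raise ParameterError("g must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.dt > 0.1 * min(self.tau_s, self.tau_theta):
            raise ParameterError(
                "dt must be small compared to the slow time constants "
                f"(dt={self.dt}, min slow tau={min(self.tau_s, self.tau_theta)})"
            )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    @property
    def tau_ratio(self) -> float:
        """The time-constant ratio ``tau_theta / tau_s``."""
        return self.tau_theta / self.tau_s

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        """Build parameters from a mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class State:
    """A point in the model's phase space.

    ``a`` is the network activity, ``s`` the fraction of undepressed
    synapses and ``theta`` the adaptation level.  The unit cube is forward
    invariant: all three steady-state sigmoids map into (0, 1), so
    trajectories started inside stay inside.
    """

    a: float
    s: float
    theta: float

    def __iter__(self) -> Iterator[float]:
        yield self.a
        yield self.s
        yield self.theta


#: Default initial condition: silent, fully recovered network.
DEFAULT_INIT = State(a=0.0, s=1.0, theta=0.0)
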