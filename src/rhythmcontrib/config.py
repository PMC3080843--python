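"""Scenario configuration: YAML/JSON parameter files and validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ParameterError
from .params import ModelParams

PROTOCOLS = ("simulate", "correlative", "blockade", "contributions",
             "sweep", "geometry", "compare")

#: Recognised protocol option keys (validated per protocol at run time).
OPTION_KEYS = ("delta_frac", "axis", "values", "threshold", "duration",
               "grid", "nullcline")


@dataclass(frozen=True)
class ScenarioConfig:
    """A validated run scenario.

    ``params`` holds the fully resolved model parameters (defaults filled
    in); ``protocol`` selects the measurement; ``options`` carries
    protocol-specific settings such as ``delta_frac`` or the sweep axis.
    """

    params: ModelParams
    protocol: str = "simulate"
    options: dict[str, Any] = field(default_factory=dict)
    out: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "ScenarioConfig":
        known_top = {"params", "protocol", "options", "out", "log_level"}
        unknown = set(raw) - known_top
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        protocol = raw.get("protocol", "simulate")
        if protocol not in PROTOCOLS:
            raise ParameterError(
                f"protocol must be one of {PROTOCOLS}, got {protocol!r}"
            )
        options = dict(raw.get("options", {}))
        bad = set(options) - set(OPTION_KEYS)
        if bad:
            raise ParameterError(f"unknown option keys: {sorted(bad)}")
        return cls(
            params=ModelParams.from_mapping(raw.get("params", {})),
            protocol=protocol,
            options=options,
            out=raw.get("out"),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        """Read a scenario from a YAML (or JSON) file."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"config root must be a mapping: {path}")
        return cls.from_mapping(raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "params": self.params.to_dict(),
            "protocol": self.protocol,
            "options": dict(self.options),
            "out": self.out,
            "log_level": self.log_level,
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
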