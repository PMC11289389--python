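"""Run configuration: YAML files merged over preset defaults.

A config file is a nested map of scalars/lists.  Recognized top-level
keys:

``preset``       one of closed / open_uncoupled / open_coupled
``overrides``    map of dotted parameter paths to numbers (units as
                 documented on :class:`~amyloop.parameters.ModelParameters`)
``m0_uM``        initial monomer concentration in micromolar
``t_end_s``      simulation horizon in seconds
``sampling``     "log" or "uniform"
``stabilization_s``  oscillation-analysis cutoff (s)
``output``       output file path

Unknown keys and non-numeric values are rejected with the offending key
named.  The fully resolved parameter set is echoed through logging.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field

import yaml

from .errors import ConfigError
from .parameters import ModelParameters, PRESET_NAMES, SystemState, preset

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "preset",
    "overrides",
    "m0_uM",
    "t_end_s",
    "sampling",
    "stabilization_s",
    "output",
    "verbosity",
}


@dataclass
class RunConfig:
    preset_name: str = "open_coupled"
    overrides: dict = dc_field(default_factory=dict)
    m0_uM: float = 0.0
    t_end_s: float = 1e5
    sampling: str = "uniform"
    stabilization_s: float = 5e4
    output: str = ""
    verbosity: int = 0

    def resolve(self) -> tuple[ModelParameters, SystemState]:
        """Apply overrides over the preset defaults and validate."""
        params, state = preset(self.preset_name)
        for path, value in self.overrides.items():
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"override {path!r} must be numeric, got {value!r}")
            params = params.set(path, float(value))
        if self.m0_uM:
            if self.m0_uM < 0:
                raise ConfigError("m0_uM must be >= 0")
            state = SystemState(a_m=self.m0_uM * 1e-6)
        log.info("resolved config %s: %s", self.digest(), params.to_flat_dict())
        return params, state

    def digest(self) -> str:
        """Short stable hash of the resolved configuration, for logging."""
        blob = json.dumps(
            {
                "preset": self.preset_name,
                "overrides": dict(sorted(self.overrides.items())),
                "m0_uM": self.m0_uM,
                "t_end_s": self.t_end_s,
                "sampling": self.sampling,
                "stabilization_s": self.stabilization_s,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Parse a YAML/JSON config file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(
        preset_name=raw.get("preset", "open_coupled"),
        overrides=dict(raw.get("overrides") or {}),
        m0_uM=float(raw.get("m0_uM", 0.0)),
        t_end_s=float(raw.get("t_end_s", 1e5)),
        sampling=raw.get("sampling", "uniform"),
        stabilization_s=float(raw.get("stabilization_s", 5e4)),
        output=raw.get("output", ""),
        verbosity=int(raw.get("verbosity", 0)),
    )
    if cfg.preset_name not in PRESET_NAMES:
        raise ConfigError(
            f"unknown preset {cfg.preset_name!r}; choose from {PRESET_NAMES}"
        )
    if cfg.sampling not in ("log", "uniform"):
        raise ConfigError(f"sampling must be 'log' or 'uniform', got {cfg.sampling!r}")
    if cfg.t_end_s < 0:
        raise ConfigError("t_end_s must be >= 0")
    cfg.resolve()  # validates overrides eagerly
    return cfg
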