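"""Model state and parameter containers.

The model tracks five state variables: free amyloid-beta (Abeta) monomer
``a_m``, oligomer ``a_o`` (in monomer equivalents), fibril particle number
concentration ``a_fp``, fibril mass concentration ``a_f`` (monomer
equivalents) — all in molar — and a dimensionless inflammation level
``infl``.

Kinetic rates that can respond to inflammation are stored as
:class:`CoupledRate` pairs ``(c0, c_inf)``: the value in the absence of
inflammation and the value at saturating inflammation.  A rate with
``c0 == c_inf`` is inflammation-independent.  In the standard configuration
only monomer generation ``k_plus`` and clearance ``k_minus`` are coupled;
every nucleation/conversion/elongation constant is stored as a constant
:class:`CoupledRate` so any of them can be made inflammation-responsive
through configuration without code changes.

Units convention: concentrations in M, time in s, ``infl`` in arbitrary
units calibrated by ``infl_ref``; ``delta_o``/``delta_f`` therefore carry
implicit units of a.u. M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import ConfigError, InputError

STATE_FIELDS = ("a_m", "a_o", "a_fp", "a_f", "infl")


@dataclass(frozen=True)
class SystemState:
    """One point of the five-variable system.

    Concentrations in M; ``infl`` dimensionless.  All fields must be
    non-negative and finite.
    """

    a_m: float = 0.0
    a_o: float = 0.0
    a_fp: float = 0.0
    a_f: float = 0.0
    infl: float = 0.0

    def __post_init__(self):
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InputError(f"state field {name} is not finite: {v!r}")
            if v < 0:
                raise InputError(f"state field {name} is negative: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_m, self.a_o, self.a_fp, self.a_f, self.infl])

    @classmethod
    def from_array(cls, y) -> "SystemState":
        y = np.asarray(y, dtype=float)
        # tolerate tiny negative integrator excursions
        y = np.where((y < 0) & (y > -1e-12), 0.0, y)
        return cls(*y)


@dataclass(frozen=True)
class CoupledRate:
    """A kinetic rate with inflammation endpoints ``c0`` (no inflammation)
    and ``c_inf`` (saturating inflammation).  ``c0 == c_inf`` encodes an
    inflammation-independent rate."""

    c0: float
    c_inf: float

    def __post_init__(self):
        if self.c0 < 0 or self.c_inf < 0:
            raise ConfigError(f"coupled rate endpoints must be >= 0, got {self}")

    @classmethod
    def constant(cls, value: float) -> "CoupledRate":
        return cls(value, value)

    @property
    def is_constant(self) -> bool:
        return self.c0 == self.c_inf


def _cr(c0, c_inf=None):
    return CoupledRate(c0, c0 if c_inf is None else c_inf)


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic, clearance, inflammation and coupling constants.

    Defaults are the standard simulation values: monomer generation
    ``k_plus`` in M s^-1, first-order clearance ``k_minus`` in s^-1,
    aggregation constants ``j1``..``j4`` with monomer kinetic orders
    ``n1``/``nconv``/``n2``, clearance attenuation factors ``gamma_o``
    (oligomer) and ``gamma_f`` (fibril), inflammation induction weights
    ``delta_o``/``delta_f``, inflammation auto-regulation ``k_infl`` (s^-1),
    and the Hill response parameters ``infl_ref`` / ``steep``.

    The conversion, elongation and secondary-nucleation back rates
    ``j_neg2``/``j_neg3``/``j_neg4`` are structurally zero (the model treats
    those steps as irreversible) and are validated as such.
    """

    k_plus: CoupledRate = field(default_factory=lambda: _cr(1e-12, 0.0))
    k_minus: CoupledRate = field(default_factory=lambda: _cr(2.78e-5, 1.39e-4))
    gamma_o: float = 0.05
    gamma_f: float = 0.01
    j1: CoupledRate = field(default_factory=lambda: _cr(6.7e-8))
    j_neg1: CoupledRate = field(default_factory=lambda: _cr(9.7e-5))
    n1: float = 0.8
    j2: CoupledRate = field(default_factory=lambda: _cr(1.9e9))
    j_neg2: float = 0.0
    nconv: float = 2.7
    j3: CoupledRate = field(default_factory=lambda: _cr(6.0e6))
    j_neg3: float = 0.0
    j4: CoupledRate = field(default_factory=lambda: _cr(2.0))
    j_neg4: float = 0.0
    n2: float = 0.9
    delta_o: float = 8e5
    delta_f: float = 2e5
    k_infl: float = 0.01
    infl_ref: float = 0.1
    steep: float = 50.0

    def __post_init__(self):
        for name in ("gamma_o", "gamma_f", "delta_o", "delta_f", "k_infl"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("n1", "nconv", "n2", "infl_ref", "steep"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("j_neg2", "j_neg3", "j_neg4"):
            if getattr(self, name) != 0.0:
                raise ConfigError(
                    f"{name} must be 0 (conversion/elongation/secondary "
                    "nucleation are irreversible in this model)"
                )

    # -- dotted-path access (used by config overrides and sweeps) ---------

    def get(self, path: str) -> float:
        """Return the value at a dotted parameter path.

        ``"gamma_o"`` returns a scalar; ``"j1.c0"`` / ``"j1.c_inf"`` address
        one endpoint of a coupled rate; a bare coupled-rate name (``"j1"``)
        is allowed only when the rate is inflammation-independent.
        """
        name, facet = _split_path(path)
        value = getattr(self, name, None)
        if value is None:
            raise ConfigError(f"unknown parameter {path!r}")
        if isinstance(value, CoupledRate):
            if facet is None:
                if not value.is_constant:
                    raise ConfigError(
                        f"{name!r} is inflammation-coupled; address "
                        f"{name}.c0 or {name}.c_inf explicitly"
                    )
                return value.c0
            return getattr(value, facet)
        if facet is not None:
            raise ConfigError(f"{name!r} has no facet {facet!r}")
        return value

    def set(self, path: str, value: float) -> "ModelParameters":
        """Return a copy with the value at ``path`` replaced.

        Setting a bare coupled-rate name sets both endpoints (the rate stays
        inflammation-independent).
        """
        name, facet = _split_path(path)
        if not hasattr(self, name):
            raise ConfigError(f"unknown parameter {path!r}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"parameter {path!r} needs a numeric value, got {value!r}")
        value = float(value)
        current = getattr(self, name)
        if isinstance(current, CoupledRate):
            if facet is None:
                new = CoupledRate.constant(value)
            else:
                new = replace(current, **{facet: value})
            return replace(self, **{name: new})
        if facet is not None:
            raise ConfigError(f"{name!r} has no facet {facet!r}")
        return replace(self, **{name: value})

    def to_flat_dict(self) -> dict:
        """Flatten to ``{dotted path: value}`` (coupled rates as two keys)."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, CoupledRate):
                out[f"{f.name}.c0"] = v.c0
                out[f"{f.name}.c_inf"] = v.c_inf
            else:
                out[f.name] = v
        return out


def _split_path(path: str):
    parts = path.split(".")
    if len(parts) == 1:
        return parts[0], None
    if len(parts) == 2 and parts[1] in ("c0", "c_inf"):
        return parts[0], parts[1]
    raise ConfigError(f"malformed parameter path {path!r}")


COUPLED_RATE_NAMES = ("k_plus", "k_minus", "j1", "j_neg1", "j2", "j3", "j4")

PRESET_NAMES = ("closed", "open_uncoupled", "open_coupled")


def preset(name: str) -> tuple[ModelParameters, SystemState]:
    """Return (parameters, initial state) for a named regime.

    ``closed``
        No generation, no clearance, no inflammation induction: the in
        vitro aggregation limit.  The caller supplies the initial monomer
        concentration.
    ``open_uncoupled``
        Physiological generation/clearance (k+ = 1e-12 M/s, k- = 2.78e-5
        s^-1, i.e. 10% per hour) with inflammation induction off; starts
        from the empty state.
    ``open_coupled``
        Full feedback loop with the fast-equilibrating generation/clearance
        pair (k+0 = 7.34e-12 M/s, k-0 = 2.78e-4, k-inf = 1.39e-3 s^-1) and
        induction weights delta_o = 8e5, delta_f = 2e5; starts from the
        empty state.
    """
    if name == "closed":
        params = ModelParameters(
            k_plus=_cr(0.0), k_minus=_cr(0.0), delta_o=0.0, delta_f=0.0
        )
        return params, SystemState()
    if name == "open_uncoupled":
        params = ModelParameters(delta_o=0.0, delta_f=0.0)
        return params, SystemState()
    if name == "open_coupled":
        params = ModelParameters(
            k_plus=_cr(7.34e-12, 0.0), k_minus=_cr(2.78e-4, 1.39e-3)
        )
        return params, SystemState()
    raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def mild_oscillation_parameters() -> ModelParameters:
    """The weakly oscillating open-coupled reference configuration.

    Open-coupled parameters with k+0 = 7e-12 M/s (k+inf = 0), steep = 50,
    infl_ref = 0.01 and k_infl = 0.003: the working point at which the
    monomer concentration shows a mild oscillation and around which the
    aggregation-parameter sweeps are run.
    """
    params, _ = preset("open_coupled")
    return replace(
        params,
        k_plus=_cr(7e-12, 0.0),
        infl_ref=0.01,
        k_infl=0.003,
    )
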