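"""Numerical integration of the model and the TimeCourse container.

The species span 1e-12 to 1e-4 M and the rate constants sixteen orders of
magnitude, so the system is stiff: integration uses LSODA (adaptive
stiff/non-stiff switching) with rtol 1e-8 and per-component atol of
1e-20 M for the four concentrations and 1e-10 for the inflammation level.

Two sampling plans cover the two analysis styles: a log-spaced grid for
aggregation kinetics resolved over 1e0-1e7 s, and a uniform 1 s grid for
oscillation analysis (the peak detector's default smoothing width is
derived from the sample count, so the uniform plan is part of the
measurement protocol, not just a convenience).
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DivergenceError, InputError, IntegrationError
from .kinetics import make_rhs
from .parameters import (
    STATE_FIELDS,
    ModelParameters,
    SystemState,
    preset,
)

log = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
ATOL_CONC = 1e-20  # M, per concentration component
ATOL_INFL = 1e-10
BLOWUP_M = 1.0  # M; a concentration above this means divergence

CSV_HEADER = ["time_s", "a_m_M", "a_o_M", "a_fp_M", "a_f_M", "infl"]


@dataclass(frozen=True)
class LogSampling:
    """Log-spaced sample times from ``t_min`` to t_end (plus t = 0)."""

    n: int = 600
    t_min: float = 1.0


@dataclass(frozen=True)
class UniformSampling:
    """Uniform grid with spacing ``dt`` from ``t_start`` to t_end."""

    dt: float = 1.0
    t_start: float = 0.0


@dataclass
class TimeCourse:
    """A sampled trajectory: ``times`` (s) and a (n, 5) ``states`` array in
    the order a_m, a_o, a_fp, a_f (M), infl (a.u.)."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    preset_name: str = ""
    _dense: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 5):
            raise InputError("states must have shape (len(times), 5)")

    def column(self, name: str) -> np.ndarray:
        try:
            return self.states[:, STATE_FIELDS.index(name)]
        except ValueError:
            raise InputError(f"unknown state field {name!r}") from None

    @property
    def a_m(self):
        return self.states[:, 0]

    @property
    def a_o(self):
        return self.states[:, 1]

    @property
    def a_fp(self):
        return self.states[:, 2]

    @property
    def a_f(self):
        return self.states[:, 3]

    @property
    def infl(self):
        return self.states[:, 4]

    def state_at(self, index: int) -> SystemState:
        return SystemState.from_array(np.clip(self.states[index], 0.0, None))

    def sample(self, times) -> np.ndarray:
        """Evaluate the dense solution at arbitrary times (n, 5)."""
        if self._dense is None:
            raise InputError("trajectory was not stored with a dense solution")
        times = np.asarray(times, dtype=float)
        return np.clip(self._dense(times).T, 0.0, None)

    def to_csv(self, path_or_buf) -> None:
        """Write the delimited time-course (full double precision)."""
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            w = csv.writer(fh)
            w.writerow(CSV_HEADER)
            for t, row in zip(self.times, self.states):
                w.writerow([repr(float(t))] + [repr(float(v)) for v in row])
        finally:
            if own:
                fh.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def simulate(
    params: ModelParameters,
    initial: SystemState,
    t_end: float,
    sampling: Optional[LogSampling | UniformSampling] = None,
    rtol: float = DEFAULT_RTOL,
    atol_conc: float = ATOL_CONC,
    atol_infl: float = ATOL_INFL,
    preset_name: str = "",
    dense: bool = True,
) -> TimeCourse:
    """Integrate the model over [0, t_end] and sample the trajectory.

    Raises :class:`IntegrationError` if the solver fails and
    :class:`DivergenceError` if any concentration exceeds 1 M.  Sampled
    states are clamped at zero on output (the integrator may make
    sub-atol negative excursions).
    """
    if t_end < 0:
        raise InputError("t_end must be >= 0")
    y0 = initial.as_array()
    if t_end == 0:
        return TimeCourse(np.array([0.0]), y0[None, :], params, preset_name)
    if sampling is None:
        sampling = LogSampling()
    t_eval = _sample_times(sampling, t_end)

    f = make_rhs(params)

    def blowup(t, y):
        return BLOWUP_M - max(y[0], y[1], y[2], y[3])

    blowup.terminal = True
    blowup.direction = -1

    atol = np.array([atol_conc] * 4 + [atol_infl])
    sol = solve_ivp(
        f,
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=dense,
        events=[blowup],
    )
    log.debug(
        "simulate t_end=%g: status=%d nfev=%d njev=%d", t_end, sol.status, sol.nfev, sol.njev
    )
    if sol.status == 1:  # terminated by the blow-up event
        t_ev = sol.t_events[0][0] if sol.t_events[0].size else None
        raise DivergenceError(
            f"concentration exceeded {BLOWUP_M} M during integration", failure_time=t_ev
        )
    if sol.status != 0:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"solver failed: {sol.message}", failure_time=float(t_fail)
        )
    states = np.clip(sol.y.T, 0.0, None)
    return TimeCourse(sol.t, states, params, preset_name, _dense=sol.sol if dense else None)


def _sample_times(sampling, t_end: float) -> np.ndarray:
    if isinstance(sampling, LogSampling):
        if t_end <= sampling.t_min:
            return np.linspace(0.0, t_end, max(sampling.n, 2))
        ts = np.logspace(np.log10(sampling.t_min), np.log10(t_end), sampling.n)
        ts[-1] = t_end
        return np.concatenate([[0.0], ts])
    if isinstance(sampling, UniformSampling):
        if sampling.t_start < 0 or sampling.t_start >= t_end:
            raise InputError("uniform sampling window start must lie in [0, t_end)")
        n = int(round((t_end - sampling.t_start) / sampling.dt))
        return sampling.t_start + sampling.dt * np.arange(n + 1)
    raise InputError(f"unknown sampling plan {sampling!r}")


def simulate_preset(
    name: str,
    m0: float = 0.0,
    t_end: float = 1e7,
    sampling=None,
    overrides: Optional[dict] = None,
) -> TimeCourse:
    """Convenience wrapper: run a named preset with initial monomer ``m0``
    (M) and optional ``{dotted path: value}`` parameter overrides."""
    params, state = preset(name)
    for path, value in (overrides or {}).items():
        params = params.set(path, value)
    if m0:
        state = SystemState(a_m=m0)
    return simulate(params, state, t_end, sampling=sampling, preset_name=name)
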