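"""Scaled steady-state sensitivities (elasticities) of the species.

At a non-oscillatory steady state the scaled sensitivity of species
concentration y to parameter x is the dimensionless elasticity
(dy/dx) * (x/y), estimated here by central finite differences with a
relative step (default 1e-3): each parameter is perturbed to (1 +/- h) x,
the steady state recomputed, and the elasticity formed from the two
states.  Parameters with value zero have no perturbation scale and are
reported as 0 by convention; entries where y = 0 are reported missing
(NaN).  Kinetic orders (exponents) are excluded.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SteadyStateError
from .oscillation import summarize_series
from .parameters import STATE_FIELDS, ModelParameters, SystemState
from .simulate import simulate

log = logging.getLogger(__name__)

DEFAULT_T_EVAL = 1e6  # s

#: parameter columns: every rate / attenuation / coupling constant, no exponents
SENSITIVITY_PARAMETERS = (
    "k_plus.c0",
    "k_plus.c_inf",
    "k_minus.c0",
    "k_minus.c_inf",
    "gamma_o",
    "gamma_f",
    "j1.c0",
    "j_neg1.c0",
    "j2.c0",
    "j3.c0",
    "j4.c0",
    "delta_o",
    "delta_f",
    "k_infl",
)


@dataclass
class SensitivityMatrix:
    species: tuple
    parameters: tuple
    values: np.ndarray  # (n_species, n_parameters), NaN = missing
    eval_time: float
    steady_state: SystemState
    rel_step: float
    notes: dict

    def to_csv(self, path_or_buf) -> None:
        """CSV matrix with a metadata header block (# lines)."""
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            fh.write(f"# eval_time_s,{self.eval_time!r}\n")
            fh.write(f"# rel_step,{self.rel_step!r}\n")
            for key, val in self.notes.items():
                fh.write(f"# {key},{val}\n")
            w = csv.writer(fh)
            w.writerow(["species"] + list(self.parameters))
            for name, row in zip(self.species, self.values):
                w.writerow([name] + [repr(float(v)) for v in row])
        finally:
            if own:
                fh.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def steady_state(
    params: ModelParameters,
    t_eval: float = DEFAULT_T_EVAL,
    initial: SystemState = None,
    check_oscillation: bool = True,
    settle_tol: float = 0.01,
) -> SystemState:
    """State at ``t_eval`` after verifying it is a settled fixed point.

    Raises :class:`SteadyStateError` when the trailing window is in steady
    oscillation; attaches a ``UserWarning`` when some nonzero component
    still drifts by more than ``settle_tol`` relative over ``t_eval``
    (|da/dt| * t_eval / a >= settle_tol).
    """
    initial = initial if initial is not None else SystemState()
    tc = simulate(params, initial, t_eval, preset_name="steady_state")
    final = tc.state_at(-1)

    if check_oscillation:
        window = min(1e5, t_eval / 2.0)
        t0 = t_eval - window
        times = t0 + np.arange(int(window) + 1, dtype=float)
        a_m = tc.sample(times)[:, 0]
        summary = summarize_series(times, a_m, stabilization_s=t0)
        if summary.regime == "steady_oscillation":
            raise SteadyStateError(
                f"dynamics are oscillatory (period ~{summary.period_s:.0f} s); "
                "no steady state exists at these parameters"
            )

    from .kinetics import rhs  # local import to avoid cycle at module load

    dy = rhs(final, params)
    y = final.as_array()
    for name, deriv in zip(STATE_FIELDS, dy.values()):
        yi = y[STATE_FIELDS.index(name)]
        if yi > 0 and abs(deriv) * t_eval / yi >= settle_tol:
            warnings.warn(
                f"steady state not fully settled: |d{name}/dt|*t/{name} = "
                f"{abs(deriv) * t_eval / yi:.2g} at t = {t_eval:g} s",
                UserWarning,
                stacklevel=2,
            )
    return final


def scaled_sensitivities(
    params: ModelParameters,
    rel_step: float = 1e-3,
    t_eval: float = DEFAULT_T_EVAL,
    parameters=SENSITIVITY_PARAMETERS,
    preset_name: str = "",
) -> SensitivityMatrix:
    """Central-difference elasticity matrix at the steady state of
    ``params``.

    The base steady state is checked for oscillation; perturbed points
    reuse the settled-fixed-point assumption.  Failures at a perturbed
    point mark the whole column missing with a reason in ``notes``.
    """
    base_state = steady_state(params, t_eval=t_eval, check_oscillation=True)
    y_base = base_state.as_array()
    values = np.full((len(STATE_FIELDS), len(parameters)), np.nan)
    notes = {}
    if preset_name:
        notes["preset"] = preset_name

    for j, path in enumerate(parameters):
        x = params.get(path)
        if x == 0.0:
            values[:, j] = 0.0  # zero perturbation scale, by convention
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                y_hi = steady_state(
                    params.set(path, x * (1.0 + rel_step)),
                    t_eval=t_eval,
                    check_oscillation=False,
                ).as_array()
                y_lo = steady_state(
                    params.set(path, x * (1.0 - rel_step)),
                    t_eval=t_eval,
                    check_oscillation=False,
                ).as_array()
        except Exception as exc:  # recorded, not fatal
            notes[f"failed:{path}"] = str(exc)
            continue
        dy = (y_hi - y_lo) / (2.0 * rel_step * x)
        with np.errstate(divide="ignore", invalid="ignore"):
            col = dy * x / y_base
        col[y_base == 0.0] = np.nan
        values[:, j] = col

    return SensitivityMatrix(
        species=STATE_FIELDS,
        parameters=tuple(parameters),
        values=values,
        eval_time=t_eval,
        steady_state=base_state,
        rel_step=rel_step,
        notes=notes,
    )
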