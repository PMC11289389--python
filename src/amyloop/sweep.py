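"""Bifurcation parameter sweeps and the 3-parameter contour grid.

A sweep varies one parameter over a grid (all others fixed), runs the
open-coupled system from the empty state for each value, and summarizes
the monomer oscillations after the stabilization period.  Bifurcations
are located purely by simulation: a regime change between two adjacent
grid points brackets a boundary to within one grid step.

Some sweep conventions tie a second parameter to the swept one (for
example the saturating clearance rate follows the intrinsic one as
``k_minus.c_inf = 5 * k_minus.c0``); these are explicit ``linked`` rules
on the spec rather than hidden conventions.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import AmyloopError, InputError, SweepError
from .oscillation import (
    DEFAULT_STABILIZATION_S,
    OscillationSummary,
    summarize,
)
from .parameters import ModelParameters, SystemState
from .simulate import TimeCourse, UniformSampling, simulate

log = logging.getLogger(__name__)

#: default analysis horizon (s): uniform 1 s sampling over [0, t_end]
DEFAULT_T_END = 1e5

BIFURCATION_CSV_HEADER = ["param", "value", "period_s", "norm_amplitude", "regime"]


def grid_values(lo: float, hi: float, n: int, spacing: str = "linear") -> np.ndarray:
    """Build an explicit grid; ``spacing`` is ``linear`` or ``log``."""
    if n < 1 or hi < lo:
        raise InputError("need n >= 1 and hi >= lo")
    if spacing == "linear":
        return np.linspace(lo, hi, n)
    if spacing == "log":
        if lo <= 0:
            raise InputError("log spacing requires lo > 0")
        return np.logspace(np.log10(lo), np.log10(hi), n)
    raise InputError(f"unknown spacing {spacing!r}")


#: common linked-parameter rules
LINK_KMINUS_INF_5X = ("k_minus.c_inf", lambda v: 5.0 * v)
LINK_KPLUS_INF_ZERO = ("k_plus.c_inf", lambda v: 0.0)


@dataclass
class SweepSpec:
    """One-dimensional sweep specification.

    ``param_path`` is a dotted name into :class:`ModelParameters`
    (``"gamma_o"``, ``"k_infl"``, ``"k_plus.c0"`` ...); ``values`` the
    explicit grid; ``linked`` optional ``(target_path, fn)`` rules applied
    per point with the swept value as argument.
    """

    param_path: str
    values: Sequence[float]
    base: ModelParameters
    linked: Sequence[tuple] = ()
    field_name: str = "a_m"
    t_end: float = DEFAULT_T_END
    stabilization_s: float = DEFAULT_STABILIZATION_S
    initial: SystemState = field(default_factory=SystemState)
    store_traces: bool = False
    trace_decimation: int = 10

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.size == 0 or not np.all(np.isfinite(values)):
            raise InputError("sweep values must be a non-empty finite list")
        self.values = values
        self.params_at(float(values[0]))  # fail fast on unknown paths

    def params_at(self, value: float) -> ModelParameters:
        p = self.base.set(self.param_path, value)
        for target, fn in self.linked:
            p = p.set(target, fn(value))
        return p


@dataclass
class SweepResult:
    spec: SweepSpec
    summaries: list  # per-value OscillationSummary or None on failure
    errors: list  # per-value error message or None
    traces: Optional[list] = None  # per-value decimated (times, a_m) or None

    def table(self):
        rows = []
        for v, s in zip(self.spec.values, self.summaries):
            if s is None:
                rows.append((v, np.nan, np.nan, "error"))
            else:
                rows.append((v, s.period_s, s.normalized_amplitude, s.regime))
        return rows

    def to_csv(self, path_or_buf) -> None:
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            w = csv.writer(fh)
            w.writerow(BIFURCATION_CSV_HEADER)
            for v, period, amp, regime in self.table():
                w.writerow(
                    [self.spec.param_path, repr(float(v)), repr(float(period)),
                     repr(float(amp)), regime]
                )
        finally:
            if own:
                fh.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def _run_point(spec: SweepSpec, value: float):
    params = spec.params_at(float(value))
    tc = simulate(
        params,
        spec.initial,
        spec.t_end,
        sampling=UniformSampling(dt=1.0),
        preset_name=f"sweep:{spec.param_path}={value:g}",
        dense=False,
    )
    summary = summarize(tc, field=spec.field_name, stabilization_s=spec.stabilization_s)
    trace = None
    if spec.store_traces:
        d = spec.trace_decimation
        trace = (tc.times[::d].copy(), tc.column(spec.field_name)[::d].copy())
    return summary, trace


def sweep_1d(spec: SweepSpec) -> SweepResult:
    """Run the open-coupled simulation and oscillation summary at every
    grid value.  Per-point failures are recorded; the sweep only raises
    :class:`SweepError` when more than half the points fail."""
    summaries, errors, traces = [], [], []
    for value in spec.values:
        try:
            summary, trace = _run_point(spec, value)
            summaries.append(summary)
            errors.append(None)
            traces.append(trace)
        except AmyloopError as exc:
            log.warning("sweep point %s=%g failed: %s", spec.param_path, value, exc)
            summaries.append(None)
            errors.append(str(exc))
            traces.append(None)
    n_fail = sum(e is not None for e in errors)
    if n_fail > len(errors) / 2:
        raise SweepError(
            f"{n_fail}/{len(errors)} sweep points failed for {spec.param_path}"
        )
    return SweepResult(
        spec=spec,
        summaries=summaries,
        errors=errors,
        traces=traces if spec.store_traces else None,
    )


@dataclass
class Grid3Result:
    """Results of the (k_infl x steep x infl_ref) grid.

    ``summaries[i][j][k]`` corresponds to steep[i], infl_ref[j], k_infl[k];
    ``traces`` (if stored) has the same nesting with decimated monomer
    window traces, exportable as one slab per (steep, k_infl) pair.
    """

    k_infl_values: np.ndarray
    steep_values: np.ndarray
    infl_ref_values: np.ndarray
    summaries: list
    traces: Optional[list] = None
    trace_times: Optional[np.ndarray] = None

    def summary_at(self, i_steep: int, j_ref: int, k_kinfl: int) -> OscillationSummary:
        return self.summaries[i_steep][j_ref][k_kinfl]

    def export_contours(self, directory) -> None:
        """One delimited slab per (steep, k_infl): rows = infl_ref values,
        columns = time samples, plus a JSON sidecar with the axes."""
        import pathlib

        if self.traces is None:
            raise InputError("grid was run without stored traces")
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, steep in enumerate(self.steep_values):
            for k, kinfl in enumerate(self.k_infl_values):
                slab = np.array(
                    [self.traces[i][j][k] for j in range(len(self.infl_ref_values))]
                )
                name = f"contour_steep{steep:g}_kinfl{kinfl:g}"
                np.savetxt(directory / f"{name}.csv", slab, delimiter=",")
        sidecar = {
            "time_s": self.trace_times.tolist(),
            "steep": self.steep_values.tolist(),
            "k_infl": self.k_infl_values.tolist(),
            "infl_ref": self.infl_ref_values.tolist(),
            "slab_rows": "infl_ref",
            "slab_columns": "time_s",
            "value": "a_m_M",
        }
        (directory / "axes.json").write_text(json.dumps(sidecar, indent=1))


def sweep_grid3(
    k_infl_values,
    steep_values,
    infl_ref_values,
    base: ModelParameters,
    t_end: float = DEFAULT_T_END,
    stabilization_s: float = DEFAULT_STABILIZATION_S,
    store_traces: bool = False,
    trace_start_s: float = 5000.0,
    trace_decimation: int = 50,
    max_points: int = 10_000,
) -> Grid3Result:
    """Exhaustive 3-parameter grid over the inflammation parameters.

    Each cell runs the open-coupled system from the empty state and
    attaches an :class:`OscillationSummary`; when ``store_traces`` is on,
    the monomer trace after ``trace_start_s`` (decimated) is kept for
    contour-map export.
    """
    k_infl_values = np.asarray(k_infl_values, dtype=float)
    steep_values = np.asarray(steep_values, dtype=float)
    infl_ref_values = np.asarray(infl_ref_values, dtype=float)
    n_total = k_infl_values.size * steep_values.size * infl_ref_values.size
    if n_total == 0:
        raise InputError("all three grids must be non-empty")
    if n_total > max_points:
        raise InputError(
            f"grid has {n_total} points, above the configured budget {max_points}"
        )
    trace_times = None
    summaries, traces = [], []
    for steep in steep_values:
        row_s, row_t = [], []
        for iref in infl_ref_values:
            cell_s, cell_t = [], []
            for kinfl in k_infl_values:
                params = replace(base, steep=float(steep), infl_ref=float(iref),
                                 k_infl=float(kinfl))
                tc = simulate(
                    params,
                    SystemState(),
                    t_end,
                    sampling=UniformSampling(dt=1.0),
                    dense=False,
                )
                cell_s.append(summarize(tc, stabilization_s=stabilization_s))
                if store_traces:
                    mask = tc.times >= trace_start_s
                    tsel = tc.times[mask][::trace_decimation]
                    cell_t.append(tc.a_m[mask][::trace_decimation])
                    if trace_times is None:
                        trace_times = tsel
            row_s.append(cell_s)
            row_t.append(cell_t)
        summaries.append(row_s)
        traces.append(row_t)
    return Grid3Result(
        k_infl_values=k_infl_values,
        steep_values=steep_values,
        infl_ref_values=infl_ref_values,
        summaries=summaries,
        traces=traces if store_traces else None,
        trace_times=trace_times,
    )


def classify_bifurcation(result: SweepResult) -> list:
    """Regime-transition boundaries of a 1-D sweep.

    Returns ``[((v_lo, v_hi), "regime_lo->regime_hi"), ...]`` for every
    pair of adjacent grid points whose regimes differ; an empty list for a
    regime-constant sweep.
    """
    boundaries = []
    values = result.spec.values
    regimes = [
        (s.regime if s is not None else "error") for s in result.summaries
    ]
    for i in range(len(regimes) - 1):
        if regimes[i] != regimes[i + 1]:
            boundaries.append(
                ((float(values[i]), float(values[i + 1])), f"{regimes[i]}->{regimes[i + 1]}")
            )
    return boundaries
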