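"""In vitro-style aggregation observables from closed-system runs.

A closed run (no generation, no clearance) converts monomer irreversibly
into fibril mass along a sigmoidal curve.  The standard experimental
summary fits a symmetric logistic ``L / (1 + exp(-k (t - t0)))`` to the
fibril mass fraction: the growth constant ``k`` is the aggregation rate,
and the t-axis intercept of the inflection tangent, ``t0 - 2/k``, is the
lag time.  Regressing log10(rate) and log10(lag) on log10(initial monomer
concentration) yields the apparent molecular orders of the aggregation
network.

The logistic is fitted on a uniform time grid spanning each curve's own
sigmoid (resampled from the dense ODE solution).  A single log-spaced grid
would weight the early decades far more heavily for fast curves; uniform
sampling matches how uniformly sampled kinetic traces are ordinarily fit.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import FitError, InputError
from .parameters import SystemState, preset
from .simulate import LogSampling, TimeCourse, simulate

#: Initial monomer concentrations (uM) of the standard closed-system ladder.
LADDER_UM = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)

#: 5-point sub-ladder for fast test runs.
FAST_LADDER_UM = (0.01, 0.1, 1.0, 10.0, 100.0)

SCAN_CSV_HEADER = [
    "m0_uM",
    "agg_rate_per_s",
    "lag_time_s",
    "final_avg_length",
    "peak_oligomer_pct",
]


@dataclass(frozen=True)
class LogisticFit:
    plateau: float
    growth_rate: float
    midpoint_time: float
    lag_time: float
    residual_norm: float


@dataclass(frozen=True)
class ScalingFit:
    exponent: float
    intercept: float
    r_squared: float
    points: tuple


@dataclass(frozen=True)
class RelativePopulation:
    """Percent-of-total trajectory for one species, with peak statistics:
    ``peak_pct`` is the maximum and ``half_max_span_s`` the (first, last)
    times at which the fraction exceeds half its maximum."""

    fraction_pct: np.ndarray
    peak_pct: float
    half_max_span_s: tuple


def _logistic(t, plateau, k, t0):
    return plateau / (1.0 + np.exp(-np.clip(k * (t - t0), -700.0, 700.0)))


def fit_logistic(times, signal) -> LogisticFit:
    """Least-squares fit of a rising symmetric logistic.

    ``signal`` should be the fibril mass fraction (0-1 scale); at least 10
    samples are required and the signal must actually rise.  Initial
    guesses: plateau = max(signal), t0 = time of half-plateau, k = 4 *
    max slope / plateau.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if times.size < 10:
        raise InputError("need at least 10 samples for a logistic fit")
    if times.size != signal.size:
        raise InputError("times and signal must have the same length")
    top = float(np.max(signal))
    if top <= 0 or top - float(np.min(signal)) < 1e-12 * max(top, 1.0):
        raise FitError("signal has no rising sigmoid (flat or non-positive)")
    slope = float(np.max(np.gradient(signal, times)))
    if slope <= 0:
        raise FitError("signal never increases; no sigmoid to fit")
    k0 = 4.0 * slope / top
    t0_guess = float(times[np.searchsorted(signal, top / 2.0, side="left").clip(0, times.size - 1)])
    try:
        popt, _ = curve_fit(
            _logistic, times, signal, p0=[top, k0, t0_guess], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    plateau, k, t0 = (float(v) for v in popt)
    if k <= 0 or plateau <= 0:
        raise FitError(
            f"non-physical logistic fit (plateau={plateau:.3g}, growth={k:.3g})"
        )
    resid = signal - _logistic(times, *popt)
    return LogisticFit(
        plateau=plateau,
        growth_rate=k,
        midpoint_time=t0,
        lag_time=t0 - 2.0 / k,
        residual_norm=float(np.linalg.norm(resid)),
    )


def fit_logistic_timecourse(
    tc: TimeCourse, total: float, n_fit: int = 4001
) -> LogisticFit:
    """Fit the fibril mass fraction of a closed run on a uniform grid
    covering the sigmoid (up to the time of 99.9% of plateau)."""
    frac = tc.a_f / total
    top = float(frac.max())
    if top <= 0:
        raise FitError("no fibril mass formed; nothing to fit")
    i_end = int(np.argmax(frac >= 0.999 * top))
    t_end = float(tc.times[i_end]) if i_end else float(tc.times[-1])
    grid = np.linspace(0.0, t_end, n_fit)[1:]
    try:
        values = tc.sample(grid)[:, 3] / total
    except InputError:
        # no dense solution stored; fall back to the sampled grid
        grid, values = tc.times, frac
    return fit_logistic(grid, values)


def scaling_exponents(
    fits: Sequence[LogisticFit], concentrations: Sequence[float]
) -> tuple[ScalingFit, ScalingFit]:
    """OLS on double-log axes: (rate exponent fit, lag exponent fit).

    ``concentrations`` are the initial monomer concentrations (M or any
    proportional unit; the exponent is unit-free).
    """
    if len(fits) != len(concentrations):
        raise InputError("one fit per concentration required")
    if len(fits) < 3:
        raise FitError("need at least 3 concentrations for a scaling fit")
    conc = np.asarray(concentrations, dtype=float)
    rates = np.array([f.growth_rate for f in fits])
    lags = np.array([f.lag_time for f in fits])
    if np.any(conc <= 0) or np.any(rates <= 0) or np.any(lags <= 0):
        raise FitError("scaling fits require positive concentrations, rates and lags")

    def ols(y):
        r = linregress(np.log10(conc), np.log10(y))
        return ScalingFit(
            exponent=float(r.slope),
            intercept=float(r.intercept),
            r_squared=float(r.rvalue**2),
            points=tuple(zip(conc.tolist(), y.tolist())),
        )

    return ols(rates), ols(lags)


def relative_population(
    tc: TimeCourse, species: str, total: float
) -> RelativePopulation:
    """Species concentration as percent of the total monomer mass.

    ``species`` is one of ``monomer``/``oligomer``/``fibril`` and ``total``
    the initial monomer concentration (M) of the closed run.
    """
    if total <= 0:
        raise InputError("total must be > 0")
    col = {"monomer": "a_m", "oligomer": "a_o", "fibril": "a_f"}.get(species)
    if col is None:
        raise InputError(f"unknown species {species!r}")
    pct = 100.0 * tc.column(col) / total
    peak = float(pct.max())
    above = pct > peak / 2.0
    if peak > 0 and above.any():
        idx = np.nonzero(above)[0]
        span = (float(tc.times[idx[0]]), float(tc.times[idx[-1]]))
    else:
        span = (np.nan, np.nan)
    return RelativePopulation(fraction_pct=pct, peak_pct=peak, half_max_span_s=span)


def average_fibril_length(a_f, a_fp):
    """Mean number of monomers per fibril, ``a_f / a_fp``.

    Vectorized; positions with ``a_fp == 0`` (pre-nucleation) are returned
    as NaN rather than raising.
    """
    a_f = np.asarray(a_f, dtype=float)
    a_fp = np.asarray(a_fp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(a_fp > 0, a_f / np.where(a_fp > 0, a_fp, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class LadderScan:
    """Per-concentration aggregation summary for a closed-system ladder."""

    m0_uM: np.ndarray
    fits: list
    final_avg_length: np.ndarray
    peak_oligomer_pct: np.ndarray

    @property
    def rates(self):
        return np.array([f.growth_rate for f in self.fits])

    @property
    def lags(self):
        return np.array([f.lag_time for f in self.fits])

    def exponents(self) -> tuple[ScalingFit, ScalingFit]:
        return scaling_exponents(self.fits, self.m0_uM * 1e-6)

    def to_csv(self, path_or_buf) -> None:
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            w = csv.writer(fh)
            w.writerow(SCAN_CSV_HEADER)
            for m0, f, length, pct in zip(
                self.m0_uM, self.fits, self.final_avg_length, self.peak_oligomer_pct
            ):
                w.writerow(
                    [repr(float(m0)), repr(f.growth_rate), repr(f.lag_time),
                     repr(float(length)), repr(float(pct))]
                )
        finally:
            if own:
                fh.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def closed_ladder_scan(
    concentrations_uM: Sequence[float] = LADDER_UM,
    t_end: float = 1e7,
    n_samples: int = 1200,
) -> LadderScan:
    """Run the closed system at each initial monomer concentration, fit the
    fibril curves and collect rates, lags, final average fibril lengths and
    peak oligomer fractions."""
    params, _ = preset("closed")
    fits, lengths, peaks = [], [], []
    for m0 in concentrations_uM:
        total = m0 * 1e-6
        tc = simulate(
            params,
            SystemState(a_m=total),
            t_end,
            sampling=LogSampling(n=n_samples),
            preset_name="closed",
        )
        fits.append(fit_logistic_timecourse(tc, total))
        final = tc.states[-1]
        lengths.append(average_fibril_length(final[3], final[2]))
        peaks.append(relative_population(tc, "oligomer", total).peak_pct)
    return LadderScan(
        m0_uM=np.asarray(concentrations_uM, dtype=float),
        fits=fits,
        final_avg_length=np.asarray(lengths),
        peak_oligomer_pct=np.asarray(peaks),
    )
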