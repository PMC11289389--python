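"""Oscillation detection and quantification on uniformly sampled windows.

Protocol: smooth the uniformly sampled trace with a Gaussian kernel whose
default width sigma = (log10(n)/2)^2 samples (6.25 samples for a 1e5-point
window), find peaks on the smoothed trace at maximum sensitivity (no
prominence threshold) and troughs as peaks of the negated trace, discard
extrema before the stabilization cutoff (default 50,000 s), and report the
mean spacing and mean peak-minus-trough excursion of the last five cycles.
The baseline is the midpoint of the last-five peak and trough levels, so a
signal oscillating between 0 and A has normalized amplitude exactly 2 —
the attainable maximum.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import InputError
from .simulate import TimeCourse

DEFAULT_STABILIZATION_S = 50_000.0
N_CYCLES = 5
#: steady-vs-damped thresholds: last-5 amplitudes within 10% relative
#: variation and normalized amplitude above 0.01
STEADY_REL_VARIATION = 0.10
STEADY_MIN_AMPLITUDE = 0.01

SUMMARY_CSV_HEADER = [
    "param_name",
    "param_value",
    "period_s",
    "norm_amplitude",
    "baseline",
    "regime",
    "n_peaks",
]


@dataclass(frozen=True)
class OscillationSummary:
    period_s: float
    normalized_amplitude: float
    baseline: float
    n_peaks: int
    regime: str  # monotonic | damped | steady_oscillation

    @property
    def oscillatory(self) -> bool:
        return self.regime == "steady_oscillation"


def default_sigma(n: int) -> float:
    """Default Gaussian smoothing width (in samples) for an n-point window:
    ``(log10(n) / 2)**2``."""
    if n < 2:
        return 0.0
    return (math.log10(n) / 2.0) ** 2


def smooth(signal, sigma: Optional[float] = None) -> np.ndarray:
    """Gaussian-kernel smoothing preserving length; ``sigma`` in samples
    (default from :func:`default_sigma`); ``sigma = 0`` is the identity."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 10:
        raise InputError("signal must be 1-D with at least 10 samples")
    if sigma is None:
        sigma = default_sigma(signal.size)
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    if sigma == 0:
        return signal.copy()
    return gaussian_filter1d(signal, sigma, mode="nearest")


def find_extrema(signal, times):
    """Local maxima and minima of a (smoothed) series at maximum
    sensitivity.  Troughs are found as peaks of the negated series.

    Returns ``(peak_times, peak_values, trough_times, trough_values)``;
    empty arrays when the series is monotone.
    """
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    if signal.size != times.size:
        raise InputError("signal and times must have the same length")
    ipk, _ = find_peaks(signal)
    itr, _ = find_peaks(-signal)
    return times[ipk], signal[ipk], times[itr], signal[itr]


def summarize(
    tc: TimeCourse,
    field: str = "a_m",
    stabilization_s: float = DEFAULT_STABILIZATION_S,
    sigma: Optional[float] = None,
) -> OscillationSummary:
    """Summarize oscillations of one state variable of a trajectory.

    The trajectory must be uniformly sampled (1 s grid by default
    elsewhere).  Smoothing is applied to the full trace; extrema before
    ``stabilization_s`` are discarded; period and amplitude are means over
    the last five post-cutoff cycles.  With fewer than two post-cutoff
    peaks the regime is ``monotonic``, the period NaN and the amplitude 0.
    """
    return summarize_series(
        tc.times, tc.column(field), stabilization_s=stabilization_s, sigma=sigma
    )


def summarize_series(
    times,
    signal,
    stabilization_s: float = DEFAULT_STABILIZATION_S,
    sigma: Optional[float] = None,
) -> OscillationSummary:
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if times.size < 10:
        raise InputError("need at least 10 samples")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InputError("oscillation analysis requires uniform sampling")

    sm = smooth(signal, sigma=sigma)
    pk_t, pk_v, tr_t, tr_v = find_extrema(sm, times)

    keep_p = pk_t >= stabilization_s
    keep_t = tr_t >= stabilization_s
    pk_t, pk_v = pk_t[keep_p], pk_v[keep_p]
    tr_t, tr_v = tr_t[keep_t], tr_v[keep_t]
    n_peaks = int(pk_t.size)

    if n_peaks < 2 or tr_t.size < 1:
        # no oscillation present: amplitude 0, period undefined
        return OscillationSummary(
            period_s=float("nan"),
            normalized_amplitude=0.0,
            baseline=float("nan"),
            n_peaks=n_peaks,
            regime="monotonic",
        )

    last_pk_v = pk_v[-N_CYCLES:]
    last_tr_v = tr_v[-N_CYCLES:]
    period = float(np.mean(np.diff(pk_t[-N_CYCLES:])))
    baseline = float((last_pk_v.mean() + last_tr_v.mean()) / 2.0)
    if baseline <= 0:
        norm_amp = float("nan")
    else:
        norm_amp = float((last_pk_v.mean() - last_tr_v.mean()) / baseline)

    # per-cycle amplitudes, pairing the i-th last peak with the i-th last trough
    n_pair = min(last_pk_v.size, last_tr_v.size)
    cyc_amp = last_pk_v[-n_pair:] - last_tr_v[-n_pair:]

    regime = "damped"
    if (
        n_peaks >= N_CYCLES
        and np.isfinite(norm_amp)
        and norm_amp > STEADY_MIN_AMPLITUDE
        and cyc_amp.size >= 2
        and cyc_amp.mean() > 0
        and (cyc_amp.max() - cyc_amp.min()) / cyc_amp.mean() < STEADY_REL_VARIATION
    ):
        regime = "steady_oscillation"

    return OscillationSummary(
        period_s=period,
        normalized_amplitude=norm_amp,
        baseline=baseline,
        n_peaks=n_peaks,
        regime=regime,
    )


def write_summaries_csv(path_or_buf, rows) -> None:
    """Write ``(param_name, param_value, OscillationSummary)`` rows."""
    own = isinstance(path_or_buf, (str, bytes))
    fh = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        w = csv.writer(fh)
        w.writerow(SUMMARY_CSV_HEADER)
        for name, value, s in rows:
            w.writerow(
                [
                    name,
                    repr(float(value)),
                    repr(float(s.period_s)),
                    repr(float(s.normalized_amplitude)),
                    repr(float(s.baseline)),
                    s.regime,
                    s.n_peaks,
                ]
            )
    finally:
        if own:
            fh.close()
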