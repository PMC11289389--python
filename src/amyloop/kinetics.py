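"""Right-hand side of the coupled aggregation-inflammation ODE system.

The network couples a four-species amyloid aggregation scheme (primary
nucleation, oligomer conversion, elongation, secondary nucleation, plus
generation and clearance) to a single inflammation variable through a
Hill-type response: oligomers and fibrils induce inflammation, and
inflammation in turn moves the generation and clearance rates between
their zero-inflammation and saturating values.  The loop is a negative
feedback with delay — the classic ingredient for sustained biochemical
oscillation.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError
from .parameters import CoupledRate, ModelParameters, SystemState

__all__ = ["hill_response", "effective_rate", "rhs", "make_rhs"]


def hill_response(infl: float, infl_ref: float, steep: float) -> float:
    """Hill response ``infl^steep / (infl_ref^steep + infl^steep)``.

    Maps an inflammation level to a modulation factor in [0, 1] with
    half-maximum at ``infl_ref`` and slope controlled by ``steep``.
    Exactly 0 at ``infl = 0`` and monotonically non-decreasing.
    """
    if not math.isfinite(infl) or infl < 0:
        raise InputError(f"inflammation level must be finite and >= 0, got {infl!r}")
    if infl_ref <= 0 or steep <= 0:
        raise InputError("infl_ref and steep must be > 0")
    if infl == 0.0:
        return 0.0
    # evaluate in log space to avoid overflow for infl >> infl_ref
    log_ratio = steep * math.log(infl / infl_ref)
    if log_ratio > 700.0:
        return 1.0
    if log_ratio < -700.0:
        return 0.0
    ratio = math.exp(log_ratio)
    return ratio / (1.0 + ratio)


def effective_rate(rate: CoupledRate, resp: float) -> float:
    """Interpolate a coupled rate at response level ``resp`` in [0, 1]:
    ``c0 + (c_inf - c0) * resp``."""
    if not 0.0 <= resp <= 1.0:
        raise InputError(f"response must lie in [0, 1], got {resp!r}")
    return rate.c0 + (rate.c_inf - rate.c0) * resp


def rhs(state: SystemState, params: ModelParameters) -> dict:
    """Time derivatives of all five state variables at ``state``.

    Returns a plain dict ``{field: d(field)/dt}``.  Monomer balance:
    generation, first-order clearance, primary nucleation (order ``n1``,
    reversible), the monomer share ``nconv/(1+nconv)`` of the conversion
    flux, elongation, and secondary nucleation (order ``n2`` in monomer,
    first order in fibril mass).  The oligomer receives the complementary
    ``1/(1+nconv)`` conversion share so that the closed system conserves
    total monomer mass ``a_m + a_o + a_f`` exactly.
    """
    f = make_rhs(params)
    dy = f(0.0, state.as_array())
    if not np.all(np.isfinite(dy)):
        raise InputError(f"non-finite derivative at state {state}")
    return dict(zip(("a_m", "a_o", "a_fp", "a_f", "infl"), dy))


def make_rhs(params: ModelParameters):
    """Compile ``params`` into a fast ``f(t, y) -> dy`` closure.

    State components are clamped at zero before fractional powers so that
    tiny negative integrator excursions cannot produce complex/NaN values.
    """
    kp = params.k_plus
    km = params.k_minus
    j1, jm1 = params.j1, params.j_neg1
    j2, j3, j4 = params.j2, params.j3, params.j4
    n1, nconv, n2 = params.n1, params.nconv, params.n2
    go, gf = params.gamma_o, params.gamma_f
    do, df, kinfl = params.delta_o, params.delta_f, params.k_infl
    iref, steep = params.infl_ref, params.steep
    any_coupled = not all(
        r.is_constant for r in (kp, km, j1, jm1, j2, j3, j4)
    )

    def f(t, y):
        a_m = y[0] if y[0] > 0.0 else 0.0
        a_o = y[1] if y[1] > 0.0 else 0.0
        a_fp = y[2] if y[2] > 0.0 else 0.0
        a_f = y[3] if y[3] > 0.0 else 0.0
        infl = y[4] if y[4] > 0.0 else 0.0

        if any_coupled and infl > 0.0:
            log_ratio = steep * math.log(infl / iref)
            if log_ratio > 700.0:
                resp = 1.0
            elif log_ratio < -700.0:
                resp = 0.0
            else:
                ratio = math.exp(log_ratio)
                resp = ratio / (1.0 + ratio)
        else:
            resp = 0.0
        c_kp = kp.c0 + (kp.c_inf - kp.c0) * resp
        c_km = km.c0 + (km.c_inf - km.c0) * resp
        c_j1 = j1.c0 + (j1.c_inf - j1.c0) * resp
        c_jm1 = jm1.c0 + (jm1.c_inf - jm1.c0) * resp
        c_j2 = j2.c0 + (j2.c_inf - j2.c0) * resp
        c_j3 = j3.c0 + (j3.c_inf - j3.c0) * resp
        c_j4 = j4.c0 + (j4.c_inf - j4.c0) * resp

        prim = c_j1 * a_m ** n1
        rev = c_jm1 * a_o
        conv = c_j2 * a_m ** nconv * a_o
        conv_o = conv / (1.0 + nconv)
        conv_m = conv - conv_o
        elong = c_j3 * a_m * a_fp
        sec = c_j4 * a_m ** n2 * a_f

        d_am = c_kp - c_km * a_m - prim + rev - conv_m - elong - sec
        d_ao = prim - rev - conv_o + sec - go * c_km * a_o
        d_afp = conv
        d_af = conv + elong - gf * c_km * a_f
        d_infl = do * a_o + df * a_f - kinfl * infl
        return (d_am, d_ao, d_afp, d_af, d_infl)

    return f
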