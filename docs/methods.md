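# Methods

## Model and assumptions

The brain is treated as a single well-mixed compartment of fixed volume.
Aggregation follows a nucleation–conversion–elongation scheme: primary
nucleation (rate `j1`, monomer order `n1 = 0.8`, reversible at `j_neg1`)
forms oligomers; oligomers convert irreversibly into elongation-competent
fibril particles (`j2`, monomer order `nconv = 2.7`); fibrils grow by
monomer addition (`j3`) without changing particle count; fibril surfaces
catalyze secondary nucleation of new oligomers (`j4`, monomer order
`n2 = 0.9`, first order in fibril mass).  Conversion, elongation and
secondary nucleation are irreversible (`j_neg2 = j_neg3 = j_neg4 = 0`).
Oligomer and fibril masses are tracked in monomer equivalents, so in the
closed limit (`k+ = k− = 0`) the sum `a_m + a_o + a_f` is conserved
analytically; the conversion flux is split `nconv/(1+nconv)` from the
monomer pool and `1/(1+nconv)` from the oligomer pool to make this
exact.  Fibril particles have no clearance: `a_fp` is non-decreasing.

Inflammation is a single phenomenological variable driven by oligomers
and fibrils (weights `delta_o = 8e5`, `delta_f = 2e5` a.u.·M⁻¹·s⁻¹,
oligomers counted in monomer equivalents) and relaxing at `k_infl`.
It modulates kinetic constants between a zero-inflammation value `c0`
and a saturating value `c_inf` through a Hill response (half-maximum
`infl_ref`, steepness `steep`, evaluated in log space so that extreme
`steep` values cannot overflow).  By default only monomer generation
(`k+`, suppressed by inflammation to 0) and clearance (`k−`, boosted
5-fold) are coupled; every rate is stored as a `(c0, c_inf)` pair so any
of them can be made inflammation-responsive by configuration.  The
effective `k−` also drives oligomer and fibril clearance through the
attenuation factors `gamma_o`, `gamma_f`.

Units: concentrations in M, time in s, `infl` in arbitrary units
calibrated by `infl_ref`.  `k− = 2.78e-5 s⁻¹` corresponds to a
fractional monomer clearance of 10% per hour; `k+ = 1e-12 M/s` to about
ten peptides per neuron per second at human-brain scale.

## Numerical integration

LSODA (stiff/non-stiff switching) with `rtol = 1e-8`, `atol = 1e-20 M`
per concentration and `1e-10` for `infl`; species span 1e-12–1e-4 M and
the rate constants sixteen orders of magnitude.  Tiny negative
excursions are clamped to zero inside the right-hand side before
fractional powers (they stay below `atol`; no projection events are
used).  A terminal event aborts with a divergence error if any
concentration exceeds 1 M; the inflammation variable is exempt because
it legitimately exceeds 1 in valid regimes (e.g. `infl ≈ 12` at
`k_infl = 1e-4`).  Halving the tolerances changes final monomer levels
by < 0.1%; a fixed-step RK4 reference agrees to 1e-4 relative on short
horizons.  There is no randomness anywhere: runs are bit-reproducible
given parameters and tolerances.

Two sampling plans: log-spaced (default 600 points over 1e0–1e7 s) for
aggregation kinetics, and a uniform 1 s grid for oscillation analysis.
Full-resolution storage is restricted to the analysis window to bound
memory; the dense solver interpolant is kept so metrics can resample
arbitrarily.

## Aggregation metrics

Closed-system fibril curves are normalized to the initial monomer
concentration and fitted with the symmetric logistic
`L/(1+exp(−k(t−t0)))`; the growth constant `k` is the aggregation rate
and `t0 − 2/k` (the t-axis intercept of the inflection tangent) the lag
time.  Seeding: `L = max`, `t0 =` half-maximum time,
`k = 4·max-slope/L`.  The fit grid is uniform over each curve's own
sigmoid support (up to 99.9% of plateau, 4000 points, resampled from the
dense solution): a single log-spaced grid would weight the first decades
~100× more for fast curves, whereas uniform sampling mirrors how
uniformly sampled kinetic traces are ordinarily fit.  Scaling exponents
are ordinary least squares of log10(rate) and log10(lag) against
log10(m0) over the 13-point ladder 0.01–100 µM (a 5-point sub-ladder is
provided for fast runs).  Average fibril length is `a_f/a_fp`, reported
as missing before nucleation.

## Oscillation metrics

Protocol: simulate 1e5 s at 1 s sampling, smooth the full trace with a
Gaussian kernel of width `sigma = (log10(n)/2)²` samples (6.25 for
n = 1e5), find peaks at maximum sensitivity (no prominence threshold)
and troughs as peaks of the negated trace, discard extrema before the
50,000 s stabilization cutoff, and average the last five cycles.  The
baseline is the midpoint of the last-five peak and trough levels;
normalized amplitude is (mean peak − mean trough)/baseline, so a signal
oscillating between 0 and A scores exactly 2 — the attainable maximum
(smoothing attenuates this by < 0.1%).  Regime classification:
`steady_oscillation` requires ≥ 5 post-cutoff peaks, amplitude > 0.01
and < 10% relative variation of the last-five cycle amplitudes; peaks
failing that are `damped`; fewer than two peaks is `monotonic`.  The
steady/damped thresholds are a design choice calibrated so that
slowly decaying near-threshold cases classify as damped; periods
reported for damped regimes are intrinsically less reliable (the peak
spacing of a decaying oscillation drifts).  The analysis field defaults
to the monomer concentration, which shows the clearest profiles.

## Sweeps and bifurcations

One-dimensional sweeps vary a single dotted parameter path over an
explicit grid (linear or log), run the open coupled system from the
empty state at each value and attach the oscillation summary;
linked-parameter rules (e.g. `k_minus.c_inf = 5·k_minus.c0`,
`k_plus.c_inf = 0`) are explicit objects on the spec.  Per-point
integration failures are recorded rather than fatal; a sweep aborts only
when more than half its points fail.  Bifurcations are bracketed purely
by simulation: a regime change between adjacent grid points localizes
the boundary to one grid step, so coarse grids (10–25 points, the
default here) preserve boundaries at coarse-step resolution while
full-resolution grids (200–500 points) remain available via `--steps`.  The
3-parameter grid (`k_infl × steep × infl_ref`) additionally stores
decimated monomer traces after the 5000 s transient for contour-map
export (one slab per steep/k_infl pair plus a JSON axes sidecar).

## Steady states and sensitivities

A steady state is the state at `t_eval` (default 1e6 s) after verifying
the trailing window is not in steady oscillation (oscillatory parameters
raise an error) and that nonzero components satisfy
`|da/dt|·t_eval/a < 1%` (violations attach a warning — the fibril pool
in open systems drifts on a `1/(gamma_f·k−)` timescale and may still be
creeping at 1e6 s).  Scaled sensitivities `(∂y/∂x)(x/y)` use central
differences with relative step 1e-3 (second-order accurate without
forward sensitivity ODEs; halving the step changes entries by < 1%).
Columns cover all rate, attenuation and coupling constants — for coupled
rates `c0` and `c_inf` separately — but not the kinetic orders.
Zero-valued parameters have no perturbation scale and report 0 by
convention; entries for species at zero are missing.  In the
aggregation-free open system the balance `a_m = k+/k−` gives analytic
elasticities +1/−1, reproduced to 1e-3.

## What the built-in experiments do and do not show

The closed preset emulates an in vitro aggregation assay (no exchange,
no inflammation); the open uncoupled preset adds physiological
generation/clearance; the open coupled preset closes the feedback loop,
with a faster generation/clearance pair (`7.34e-12`, `2.78e-4`/`1.39e-3`)
that shortens equilibration without materially changing the uncoupled
steady state.  These are idealizations: one compartment, no spatial
structure, no explicit immune-cell populations, no tau co-aggregation,
and a single lumped inflammation variable.

Known limitations of the model itself, verified numerically:

- Because fibril particles are never cleared, `a_fp` ratchets upward;
  large initial monomer boluses (≥ 0.9 µM) leave a permanently larger
  particle pool and settle to visibly different quasi-steady monomer
  levels, and their approach to the shared limit cycle at oscillatory
  parameters takes 2–4e5 s rather than the 5e4 s seen for small boluses.
  There is no true fixed point, only a slow drift.
- The mild-oscillation working point (`j1 = 6.7e-8` at `steep=50`,
  `infl_ref=0.01`, `k_infl=0.003`) lies just below the Hopf threshold
  (steady oscillation onsets at `j1 ≈ 1e-7`): the package classifies it
  as damped, with window-dependent measured amplitude.  The
  `gamma_o ∈ [0.01, 0.2]` band around it is likewise weakly damped
  rather than weakly steady; the non-oscillatory boundary above 0.2 is
  robust.
- At the slow-relaxation end of the `k_infl` sweep (1e-4) the period is
  set by inflammation decay from its spike value down to `infl_ref`
  and measures ~1.5e4 s with amplitude 2; the period estimate there
  keeps decreasing toward its asymptote over several 1e5 s.

Problem sizes used by the bundled test-suite and acceptance runs —
13 closed integrations to 1e7 s, single coupled runs of 1e5 s at 1 s
sampling, and 10-point sweeps — were chosen as the coarse desk-scale
protocol; every boundary statement above is bracketed at that grid
resolution.
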