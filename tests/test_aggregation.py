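"""Aggregation metrics: logistic fits, scaling exponents, populations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amyloop as al
from amyloop.aggregation import fit_logistic, LadderScan


def logistic(t, L, k, t0):
    return L / (1.0 + np.exp(-k * (t - t0)))


class TestFitLogistic:
    def test_recovers_exact_logistic(self):
        t = np.linspace(0, 4e4, 500)
        fit = fit_logistic(t, logistic(t, 1.0, 1e-3, 1e4))
        assert fit.growth_rate == pytest.approx(1e-3, rel=1e-8)
        assert fit.midpoint_time == pytest.approx(1e4, rel=1e-8)
        assert fit.lag_time == pytest.approx(8000.0, rel=1e-6)

    @given(
        logk=st.floats(-5, -1),
        logt0=st.floats(2, 6),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_recovery_across_scales(self, logk, logt0):
        k, t0 = 10.0**logk, 10.0**logt0
        t = np.linspace(max(0.0, t0 - 10 / k), t0 + 10 / k, 600)
        fit = fit_logistic(t, logistic(t, 2.5, k, t0))
        assert fit.growth_rate == pytest.approx(k, rel=1e-6)
        assert fit.midpoint_time == pytest.approx(t0, rel=1e-6)

    def test_flat_signal_raises(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(al.FitError):
            fit_logistic(t, np.zeros_like(t))

    def test_too_few_samples_rejected(self):
        with pytest.raises(al.InputError):
            fit_logistic(np.arange(5.0), np.arange(5.0))


class TestScalingExponents:
    def test_exact_power_laws(self):
        conc = np.array([0.1e-6, 1e-6, 10e-6])
        fits = [
            al.LogisticFit(1.0, 3.0 * (c / 1e-6) ** 1.5, 0.0, 7.0 * (c / 1e-6) ** -1.0, 0.0)
            for c in conc
        ]
        rate_fit, lag_fit = al.scaling_exponents(fits, conc)
        assert rate_fit.exponent == pytest.approx(1.5, abs=1e-12)
        assert lag_fit.exponent == pytest.approx(-1.0, abs=1e-12)
        assert rate_fit.r_squared == pytest.approx(1.0)

    def test_exponent_invariant_under_unit_rescaling(self):
        conc = np.array([0.1e-6, 1e-6, 10e-6])

        def make(scale):
            return [
                al.LogisticFit(1.0, scale * 3.0 * (c / 1e-6) ** 1.5, 0.0,
                               scale * 7.0 * (c / 1e-6) ** -1.2, 0.0)
                for c in conc
            ]

        r1, l1 = al.scaling_exponents(make(1.0), conc)
        r2, l2 = al.scaling_exponents(make(3600.0), conc)
        assert r1.exponent == pytest.approx(r2.exponent, abs=1e-12)
        assert l1.exponent == pytest.approx(l2.exponent, abs=1e-12)
        assert r1.intercept != r2.intercept

    def test_needs_three_points(self):
        conc = [1e-6, 2e-6]
        fits = [al.LogisticFit(1, 1, 1, 1, 0)] * 2
        with pytest.raises(al.FitError):
            al.scaling_exponents(fits, conc)


class TestPopulations:
    def test_pure_monomer_at_start(self, closed_params):
        tc = al.simulate(closed_params, al.SystemState(a_m=1e-6), 0.0)
        mono = al.relative_population(tc, "monomer", 1e-6)
        olig = al.relative_population(tc, "oligomer", 1e-6)
        assert mono.fraction_pct[0] == 100.0
        assert olig.fraction_pct[0] == 0.0

    def test_rejects_nonpositive_total(self, mild_tc):
        with pytest.raises(al.InputError):
            al.relative_population(mild_tc, "oligomer", 0.0)

    def test_unknown_species(self, mild_tc):
        with pytest.raises(al.InputError):
            al.relative_population(mild_tc, "protofibril", 1e-6)

    def test_oligomer_peak_reports_half_maximum_span(self, closed_params):
        tc = al.simulate(closed_params, al.SystemState(a_m=1e-8), 1e7)
        pop = al.relative_population(tc, "oligomer", 1e-8)
        t_lo, t_hi = pop.half_max_span_s
        assert 0 < t_lo < t_hi <= 1e7
        assert pop.peak_pct > 1.0  # low-concentration runs build up oligomers


class TestFibrilLength:
    def test_ratio_identity(self):
        assert al.average_fibril_length(1e-9, 1e-9) == 1.0

    def test_pre_nucleation_is_missing_not_error(self):
        out = al.average_fibril_length(np.array([0.0, 1e-9]), np.array([0.0, 1e-12]))
        assert np.isnan(out[0])
        assert out[1] == pytest.approx(1000.0)

    def test_non_decreasing_under_pure_elongation(self, closed_params):
        """With nucleation and conversion off, elongation can only extend
        existing fibrils, so the average length is non-decreasing."""
        params = closed_params.set("j1", 0.0).set("j2", 0.0).set("j4", 0.0)
        start = al.SystemState(a_m=1e-6, a_fp=1e-12, a_f=1e-11)
        tc = al.simulate(params, start, 1e5)
        length = al.average_fibril_length(tc.a_f, tc.a_fp)
        length = length[~np.isnan(length)]
        assert np.all(np.diff(length) >= -1e-9 * length[:-1])


class TestLadderScan:
    def test_scan_csv_has_documented_header(self, ladder_scan):
        text = ladder_scan.to_csv_string()
        assert text.splitlines()[0] == (
            "m0_uM,agg_rate_per_s,lag_time_s,final_avg_length,peak_oligomer_pct"
        )
        assert len(text.strip().splitlines()) == 14

    def test_rates_increase_and_lags_decrease_with_concentration(self, ladder_scan):
        assert np.all(np.diff(ladder_scan.rates) > 0)
        assert np.all(np.diff(ladder_scan.lags) < 0)
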