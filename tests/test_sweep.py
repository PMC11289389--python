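"""Parameter sweeps, linked rules, grid cross-checks and classification."""

import numpy as np
import pytest

import amyloop as al
from amyloop.oscillation import OscillationSummary
from amyloop.sweep import SweepResult


def _mk_summary(regime, period=1000.0, amp=1.0):
    return OscillationSummary(
        period_s=period, normalized_amplitude=amp, baseline=1.0,
        n_peaks=10, regime=regime,
    )


class TestSweepSpec:
    def test_unknown_parameter_fails_fast(self, mild_params):
        with pytest.raises(al.ConfigError):
            al.SweepSpec("k_plos.c0", [1e-12], mild_params)

    def test_empty_grid_rejected(self, mild_params):
        with pytest.raises(al.InputError):
            al.SweepSpec("gamma_o", [], mild_params)

    def test_linked_rule_binds_second_parameter(self, mild_params):
        spec = al.SweepSpec(
            "k_minus.c0", [1e-5, 1e-4], mild_params,
            linked=[al.LINK_KMINUS_INF_5X],
        )
        p = spec.params_at(1e-4)
        assert p.k_minus.c0 == 1e-4
        assert p.k_minus.c_inf == pytest.approx(5e-4)

    def test_grid_values_spacings(self):
        lin = al.grid_values(0.0, 1.0, 5)
        assert np.allclose(lin, [0, 0.25, 0.5, 0.75, 1.0])
        logg = al.grid_values(1e-4, 1e-2, 3, "log")
        assert np.allclose(logg, [1e-4, 1e-3, 1e-2])
        with pytest.raises(al.InputError):
            al.grid_values(0.0, 1.0, 3, "log")


class TestSweep1D:
    def test_inert_parameter_gives_identical_summaries(self, mild_params):
        """Fibril-clearance attenuation is dynamically negligible when the
        fibril pool is tiny; sweeping it must not change the summary."""
        spec = al.SweepSpec(
            "gamma_f", [0.01, 0.1, 1.0], mild_params, t_end=3e4,
            stabilization_s=1e4,
        )
        res = al.sweep_1d(spec)
        periods = [s.period_s for s in res.summaries]
        amps = [s.normalized_amplitude for s in res.summaries]
        assert np.allclose(periods, periods[0], rtol=1e-3)
        assert np.allclose(amps, amps[0], rtol=1e-2)

    def test_order_independent(self, mild_params):
        values = np.array([0.02, 0.08, 0.05])
        spec = al.SweepSpec("gamma_o", values, mild_params, t_end=3e4,
                            stabilization_s=1e4)
        res = al.sweep_1d(spec)
        spec_sorted = al.SweepSpec("gamma_o", np.sort(values), mild_params,
                                   t_end=3e4, stabilization_s=1e4)
        res_sorted = al.sweep_1d(spec_sorted)
        by_value = dict(zip(spec.values.tolist(), res.summaries))
        for v, s in zip(spec_sorted.values.tolist(), res_sorted.summaries):
            assert by_value[v] == s

    def test_majority_failure_raises_sweep_error(self, mild_params):
        # bare path pins both endpoints: generation stays at ~1 M/s even
        # under full inflammation, so every point diverges
        spec = al.SweepSpec("k_plus", [0.5, 1.0], mild_params, t_end=100.0,
                            stabilization_s=10.0)
        with pytest.raises(al.SweepError):
            al.sweep_1d(spec)

    def test_csv_export_schema(self, mild_params):
        spec = al.SweepSpec("gamma_o", [0.05], mild_params, t_end=2e4,
                            stabilization_s=5e3)
        text = al.sweep_1d(spec).to_csv_string()
        lines = text.strip().splitlines()
        assert lines[0] == "param,value,period_s,norm_amplitude,regime"
        assert lines[1].startswith("gamma_o,0.05,")


class TestGrid3:
    def test_degenerate_grid_matches_single_run(self, mild_params):
        res = al.sweep_grid3(
            [mild_params.k_infl], [mild_params.steep], [mild_params.infl_ref],
            mild_params, t_end=3e4, stabilization_s=1e4,
        )
        tc = al.simulate(
            mild_params, al.SystemState(), 3e4, sampling=al.UniformSampling(dt=1.0)
        )
        direct = al.summarize(tc, stabilization_s=1e4)
        assert res.summary_at(0, 0, 0) == direct

    def test_grid_cells_match_independent_1d_sweep(self, mild_params):
        kinfl_values = [0.003, 0.006]
        res = al.sweep_grid3(
            kinfl_values, [50.0], [0.01], mild_params, t_end=3e4,
            stabilization_s=1e4,
        )
        sweep = al.sweep_1d(
            al.SweepSpec("k_infl", kinfl_values, mild_params, t_end=3e4,
                         stabilization_s=1e4)
        )
        for k in range(2):
            assert res.summary_at(0, 0, k) == sweep.summaries[k]

    def test_budget_guard(self, mild_params):
        with pytest.raises(al.InputError):
            al.sweep_grid3(
                np.ones(30), np.ones(30), np.ones(30), mild_params, max_points=100
            )


class TestClassifyBifurcation:
    def test_reports_regime_changes_between_adjacent_points(self, mild_params):
        spec = al.SweepSpec("gamma_o", [0.1, 0.2, 0.3, 0.4], mild_params)
        res = SweepResult(
            spec=spec,
            summaries=[
                _mk_summary("damped"),
                _mk_summary("steady_oscillation"),
                _mk_summary("steady_oscillation"),
                _mk_summary("monotonic"),
            ],
            errors=[None] * 4,
        )
        bounds = al.classify_bifurcation(res)
        assert bounds == [
            ((0.1, 0.2), "damped->steady_oscillation"),
            ((0.3, 0.4), "steady_oscillation->monotonic"),
        ]

    def test_constant_regime_has_no_boundaries(self, mild_params):
        spec = al.SweepSpec("gamma_o", [0.1, 0.2], mild_params)
        res = SweepResult(
            spec=spec, summaries=[_mk_summary("monotonic")] * 2, errors=[None] * 2
        )
        assert al.classify_bifurcation(res) == []
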