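"""Rate calculus: averages, instantaneous profiles, phases, INB."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import nitrikin as nk
from nitrikin.boltzmann import BoltzmannResults, boltzmann_derivative
from nitrikin.exceptions import ValidationError
from nitrikin.series import IncubationSeries


def make_results(a1, a2, t0, dt, analyte="NOx"):
    """Assemble results directly from known parameters (no fitting)."""
    return BoltzmannResults(
        model=None,
        params=np.array([a1, a2, t0, dt], dtype=float),
        cov_params=np.full((4, 4), np.nan),
        rss=0.0,
        rsquared=1.0,
        nobs=0,
        analyte=analyte,
    )


class TestAverageRate:
    def test_flat_fit_has_zero_rate(self):
        fit = make_results(50, 50, 30, 5)
        assert nk.average_rate(fit, (0, 68)) == 0.0

    def test_canonical_window(self, canon_params):
        fit = make_results(*canon_params)
        assert nk.average_rate(fit, (0, 68)) == pytest.approx(1.466, abs=1e-3)

    def test_mean_below_max_on_symmetric_window(self, canon_params):
        fit = make_results(*canon_params)
        for w in (1.0, 5.0, 20.0):
            v_avg = nk.average_rate(fit, (fit.t0 - w, fit.t0 + w))
            assert 0 < v_avg < fit.peak_rate

    def test_degenerate_window_rejected(self, canon_params):
        fit = make_results(*canon_params)
        with pytest.raises(ValidationError):
            nk.average_rate(fit, (10, 10))

    def test_raw_endpoint_mode(self):
        t = np.array([0.0, 6.0, 12.0])
        y = np.array([1.0, 7.0, 25.0])
        assert nk.average_rate_raw(t, y) == pytest.approx(2.0)
        assert nk.average_rate_raw(t, y, (0, 6)) == pytest.approx(1.0)

    def test_matches_trapezoidal_mean_of_derivative(self, canon_params):
        """Fundamental-theorem consistency between the two rate routes."""
        fit = make_results(*canon_params)
        for window in [(0, 68), (10, 50), (25, 35), (40, 80)]:
            grid = np.linspace(*window, 20001)
            trapz_mean = np.trapezoid(fit.rate(grid), grid) / (window[1] - window[0])
            assert nk.average_rate(fit, window) == pytest.approx(
                trapz_mean, rel=1e-6
            )


class TestInstantaneousProfile:
    def test_interior_maximum_at_t0(self, canon_params):
        fit = make_results(*canon_params)
        prof = nk.instantaneous_profile(fit, (0, 80))
        assert prof.v_max == pytest.approx(5.0)
        assert prof.t_at_vmax == pytest.approx(30.0)
        assert prof.v_avg < prof.v_max

    def test_window_right_of_t0_peaks_at_left_edge(self, canon_params):
        fit = make_results(*canon_params)
        prof = nk.instantaneous_profile(fit, (40, 80))
        assert prof.t_at_vmax == 40.0
        assert prof.v_max == pytest.approx(2.100, abs=1e-3)

    def test_window_left_of_t0_peaks_at_right_edge(self, canon_params):
        fit = make_results(*canon_params)
        prof = nk.instantaneous_profile(fit, (0, 20))
        assert prof.t_at_vmax == 20.0

    def test_grid_and_frame(self, canon_params):
        fit = make_results(*canon_params)
        prof = nk.instantaneous_profile(fit, (0, 80), n_grid=101)
        frame = prof.to_frame()
        assert list(frame.columns) == ["time_h", "rate_umol_L_h"]
        assert len(frame) == 101
        assert frame["rate_umol_L_h"].max() <= prof.v_max + 1e-12

    def test_empty_window_rejected(self, canon_params):
        fit = make_results(*canon_params)
        with pytest.raises(ValidationError):
            nk.instantaneous_profile(fit, (50, 50))


class TestSegmentPhases:
    def test_matches_numeric_root_finding(self, canon_params):
        """Closed-form boundaries vs brentq on dy/dt = f * peak."""
        fit = make_results(*canon_params)
        for f in (0.05, 0.10, 0.5, 0.9):
            lag_end, plateau_start = nk.segment_phases(fit, threshold_frac=f)

            def g(t):
                return boltzmann_derivative(t, *fit.params) - f * fit.peak_rate

            left = brentq(g, fit.t0 - 60 * fit.dt, fit.t0, xtol=1e-12)
            right = brentq(g, fit.t0, fit.t0 + 60 * fit.dt, xtol=1e-12)
            assert lag_end == pytest.approx(left, abs=1e-8)
            assert plateau_start == pytest.approx(right, abs=1e-8)

    def test_canonical_tenth_threshold(self, canon_params):
        fit = make_results(*canon_params)
        lag_end, plateau_start = nk.segment_phases(fit, (0, 80), 0.10)
        assert lag_end == pytest.approx(11.8155, abs=1e-3)
        assert plateau_start == pytest.approx(48.1845, abs=1e-3)

    def test_symmetry_about_t0(self, canon_params):
        fit = make_results(*canon_params)
        lag_end, plateau_start = nk.segment_phases(fit, threshold_frac=0.1)
        assert (fit.t0 - lag_end) == pytest.approx(plateau_start - fit.t0, abs=1e-9)

    def test_threshold_one_collapses_to_t0(self, canon_params):
        fit = make_results(*canon_params)
        lag_end, plateau_start = nk.segment_phases(fit, threshold_frac=1.0)
        assert lag_end == plateau_start == fit.t0

    @pytest.mark.parametrize("f", [0.0, -0.5, 1.5])
    def test_bad_threshold_rejected(self, canon_params, f):
        with pytest.raises(ValidationError):
            nk.segment_phases(make_results(*canon_params), threshold_frac=f)


def series_from_rows(rows):
    return IncubationSeries(
        pd.DataFrame(
            rows,
            columns=["time_h", "replicate", "nh4_umol_L", "no2_umol_L", "no3_umol_L"],
        )
    )


class TestINB:
    def test_redistribution_without_loss_is_balanced(self):
        series = series_from_rows([(0, 1, 100, 0, 0), (6, 1, 50, 20, 30)])
        inb = nk.compute_inb(series)
        assert np.allclose(inb.inb, [1.0, 1.0])
        assert inb.labels == ["balanced", "balanced"]

    def test_loss_and_mineralization_labels(self):
        series = series_from_rows(
            [(0, 1, 100, 0, 0), (6, 1, 60, 10, 10), (12, 1, 100, 17, 20)]
        )
        inb = nk.compute_inb(series, tolerance=0.05)
        assert inb.inb[1] == pytest.approx(0.8)
        assert inb.inb[2] == pytest.approx(1.37)
        assert inb.labels == ["balanced", "loss", "mineralization"]

    def test_initial_din_zero_rejected(self):
        series = series_from_rows([(0, 1, 0, 0, 0), (6, 1, 1, 1, 1)])
        with pytest.raises(ValidationError, match="undefined"):
            nk.compute_inb(series)

    def test_closed_system_simulation_stays_at_one(self, closed_run):
        _, series, _ = closed_run
        inb = nk.compute_inb(series)
        assert inb.inb[0] == 1.0
        assert np.max(np.abs(inb.inb - 1.0)) < 1e-6
        assert set(inb.labels) == {"balanced"}

    def test_lossy_simulation_decreases_below_one(self):
        cfg = nk.get_preset("closed_system").replace(loss_rate=0.02)
        series, _ = nk.simulate_incubation(cfg)
        inb = nk.compute_inb(series)
        assert (np.diff(inb.inb) < 0).all()
        assert inb.final < 1.0 and inb.labels[-1] == "loss"

    def test_mineralizing_simulation_rises_above_one(self):
        cfg = nk.get_preset("closed_system").replace(mineralization_rate=1.0)
        series, _ = nk.simulate_incubation(cfg)
        inb = nk.compute_inb(series)
        assert (np.diff(inb.inb) > 0).all()
        assert inb.final > 1.0 and inb.labels[-1] == "mineralization"

    @given(scale=st.floats(0.1, 10))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_scale_invariance(self, scale):
        rows = [(0, 1, 100, 5, 10), (6, 1, 80, 15, 12), (12, 1, 50, 30, 28)]
        base = nk.compute_inb(series_from_rows(rows))
        scaled_rows = [(t, r, a * scale, b * scale, c * scale) for t, r, a, b, c in rows]
        scaled = nk.compute_inb(series_from_rows(scaled_rows))
        assert np.allclose(base.inb, scaled.inb, rtol=1e-12)


class TestSampleWorkflow:
    def test_sample_a_recovers_true_average_ao_rate(self, sample_a_run):
        _, series, truth = sample_a_run
        results = nk.analyze_sample(series)
        window = (float(series.times[0]), float(series.times[-1]))
        true_va = truth.average_ao(window)
        assert abs(results.ao_profile.v_avg - true_va) / true_va < 0.10
        assert results.ao_fit.rsquared > 0.99

    def test_sample_a_rate_crossover(self, sample_a_run):
        """Early ammonia oxidation outpaces nitrite oxidation, then flips."""
        _, series, _ = sample_a_run
        results = nk.analyze_sample(series)
        grid = np.linspace(series.times[0], series.times[-1], 400)
        diff = results.ao_fit.rate(grid) - results.no_fit.rate(grid)
        assert diff[0] > 0
        assert diff.min() < 0  # Vn exceeds Va later in the incubation
        sign_changes = np.sum(np.diff(np.sign(diff)) != 0)
        assert sign_changes == 1

    def test_sample_b_no_material_nitrite(self, sample_b_run):
        _, series, _ = sample_b_run
        no2 = series.analyte("NO2").groupby("time_h")["value"].mean().to_numpy()
        nh4 = series.analyte("NH4").groupby("time_h")["value"].mean().to_numpy()
        assert no2.max() - no2[0] < 0.10 * (nh4[0] - nh4.min())

    def test_sample_b_rate_maxima_at_window_start(self, sample_b_run):
        _, series, _ = sample_b_run
        results = nk.analyze_sample(series)
        assert results.ao_profile.t_at_vmax == series.times[0]
        assert results.no_profile.t_at_vmax == series.times[0]

    def test_doubling_concentrations_doubles_rates(self, sample_a_run):
        _, series, _ = sample_a_run
        doubled = series.data.copy()
        for col in ("nh4_umol_L", "no2_umol_L", "no3_umol_L"):
            doubled[col] *= 2.0
        r1 = nk.analyze_sample(series)
        r2 = nk.analyze_sample(IncubationSeries(doubled))
        assert r2.ao_profile.v_avg == pytest.approx(2 * r1.ao_profile.v_avg, rel=1e-4)
        assert r2.ao_profile.v_max == pytest.approx(2 * r1.ao_profile.v_max, rel=1e-4)
        assert np.allclose(r2.inb.inb, r1.inb.inb, rtol=1e-9)

    def test_report_tables_and_summary(self, sample_a_run):
        _, series, _ = sample_a_run
        results = nk.analyze_sample(series)
        rates = results.rates_table()
        assert list(rates["rate"]) == ["Va", "Vn"]
        assert (rates["v_max_umol_L_h"] >= rates["v_avg_umol_L_h"]).all()
        assert {"analyte", "time_h", "fitted_umol_L", "rate_umol_L_h"} <= set(
            results.curves_table().columns
        )
        text = results.summary()
        assert "Va" in text and "INB" in text

    def test_empty_series_fails_at_prepare_stage(self):
        series = series_from_rows([(0, 1, 1, 1, 1), (6, 1, 1, 1, 1)])
        with pytest.raises(ValidationError, match="stage fit:NOx"):
            nk.analyze_sample(series)

    def test_noisy_recovery_of_va_and_vmax(self):
        """Monte-Carlo: fitted V̄ₐ and v_max track the simulator truth."""
        cfg = nk.get_preset("sample_A_like")
        errs_avg, errs_max = [], []
        for seed in range(40):
            series, truth = nk.simulate_incubation(cfg.replace(seed=seed))
            res = nk.analyze_sample(series, nk.AnalysisConfig(seed=seed))
            window = (float(series.times[0]), float(series.times[-1]))
            errs_avg.append(
                abs(res.ao_profile.v_avg - truth.average_ao(window))
                / truth.average_ao(window)
            )
            errs_max.append(abs(res.ao_profile.v_max - truth.v_ao_max) / truth.v_ao_max)
        assert np.median(errs_avg) < 0.10
        assert np.median(errs_max) < 0.10
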