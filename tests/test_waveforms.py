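"""Waveform container, I/O, resampling, smoothing and foot detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from awia.errors import DetectionError, FormatError, ValidationError
from awia.waveforms import (
    WaveformSeries,
    detect_systolic_foot,
    load_waveforms,
    resample_uniform,
    smooth_area,
)


def _write_csv(path, t, U, A, header="time_ms,U_mps,A_mm2"):
    cols = header.split(",")
    pd.DataFrame({cols[0]: t, cols[1]: U, cols[2]: A}).to_csv(path, index=False)


class TestLoading:
    def test_csv_round_trip(self, tmp_path):
        t = 9.6 * np.arange(40)
        U = np.sin(t / 100)
        A = 600 + 30 * np.cos(t / 120)
        path = tmp_path / "wave.csv"
        _write_csv(path, t, U, A)
        s = load_waveforms(path)
        assert len(s) == 40
        np.testing.assert_allclose(s.t, t)
        np.testing.assert_allclose(s.U, U)
        np.testing.assert_allclose(s.A, A)

    def test_velocity_sign_flip_negates_u_only(self, tmp_path):
        t = np.arange(10, dtype=float)
        U = np.linspace(-0.2, 1.0, 10)
        A = np.full(10, 500.0)
        path = tmp_path / "wave.csv"
        _write_csv(path, t, U, A)
        s = load_waveforms(path, velocity_sign=-1)
        np.testing.assert_allclose(s.U, -U, rtol=1e-12)  # CSV text precision
        np.testing.assert_array_equal(s.A, A)

    def test_zero_area_names_the_row(self, tmp_path):
        t = np.arange(10, dtype=float)
        A = np.full(10, 500.0)
        A[7] = 0.0
        path = tmp_path / "wave.csv"
        _write_csv(path, t, np.ones(10), A)
        with pytest.raises(ValidationError, match="row 7"):
            load_waveforms(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "wave.csv"
        pd.DataFrame({"time_ms": [0, 1], "U_mps": [0, 1]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="A_mm2"):
            load_waveforms(path)

    def test_non_monotone_time_rejected(self, tmp_path):
        t = np.arange(10, dtype=float)
        t[5] = t[4]
        path = tmp_path / "wave.csv"
        _write_csv(path, t, np.ones(10), np.full(10, 500.0))
        with pytest.raises(ValidationError, match="increasing"):
            load_waveforms(path)

    def test_unit_conversion_cm2_and_cms(self, tmp_path):
        t = np.arange(10, dtype=float)
        path = tmp_path / "wave.csv"
        _write_csv(path, t, np.full(10, 50.0), np.full(10, 6.0))
        s = load_waveforms(path, units={"velocity": "cm/s", "area": "cm2"})
        np.testing.assert_allclose(s.U, 0.5)
        np.testing.assert_allclose(s.A, 600.0)

    def test_json_records(self, tmp_path):
        t = np.arange(12, dtype=float)
        df = pd.DataFrame({"time_ms": t, "U_mps": np.ones(12), "A_mm2": 500.0})
        path = tmp_path / "wave.json"
        df.to_json(path)
        s = load_waveforms(path)
        assert len(s) == 12


class TestResampling:
    def test_linear_signal_exact_both_methods(self):
        t = 9.6 * np.arange(20)
        U = 0.01 * t + 0.2
        A = 0.5 * t + 400.0
        s = WaveformSeries(t=t, U=U, A=A, dt_native=9.6)
        for method in ("monotone-cubic", "linear"):
            r = resample_uniform(s, dt=1.0, method=method)
            np.testing.assert_allclose(r.U, 0.01 * r.t + 0.2, rtol=1e-12)
            np.testing.assert_allclose(r.A, 0.5 * r.t + 400.0, rtol=1e-12)
            assert np.allclose(np.diff(r.t), 1.0)

    def test_knots_reproduced_exactly(self, quiet_forward_series):
        series, _ = quiet_forward_series
        r = resample_uniform(series, dt=0.1)
        # native knots at multiples of 9.6 ms land on the 0.1 ms grid
        idx = np.round(series.t / 0.1).astype(int)
        np.testing.assert_allclose(r.U[idx], series.U, atol=1e-9)
        np.testing.assert_allclose(r.A[idx], series.A, atol=1e-6)

    def test_monotone_cubic_no_overshoot(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 500, 30))
        t[0], t[-1] = 0.0, 500.0
        A = np.cumsum(rng.uniform(0.5, 5.0, 30)) + 400.0  # monotone knots
        s = WaveformSeries(t=t, U=np.linspace(0, 1, 30), A=A, dt_native=float(np.min(np.diff(t))))
        r = resample_uniform(s, dt=0.25 * float(np.min(np.diff(t))))
        # shape preservation: between consecutive knots the interpolant stays
        # within the bracketing knot values
        for i in range(len(t) - 1):
            mask = (r.t >= t[i]) & (r.t <= t[i + 1])
            assert np.all(r.A[mask] >= A[i] - 1e-9)
            assert np.all(r.A[mask] <= A[i + 1] + 1e-9)

    def test_interpolation_choice_immaterial_for_wave_speed(self, quiet_forward_series):
        from awia.pipeline import analyze_series

        series, truth = quiet_forward_series
        cs = {}
        for method in ("monotone-cubic", "linear"):
            rep = analyze_series(series, interpolation=method, sg_window=None)
            cs[method] = rep.wave_speed.c
        assert abs(cs["monotone-cubic"] - cs["linear"]) / cs["linear"] < 0.02

    def test_downsampling_refused(self, quiet_forward_series):
        series, _ = quiet_forward_series
        with pytest.raises(ValidationError, match="coarser"):
            resample_uniform(series, dt=20.0)


class TestSmoothing:
    def test_exact_cubic_reproduced(self):
        t = np.arange(300, dtype=float)
        A = 1e-4 * (t - 150) ** 3 + 0.05 * (t - 100) ** 2 + 500.0
        s = WaveformSeries(t=t, U=np.zeros(300), A=A, dt_native=1.0)
        out = smooth_area(s)
        np.testing.assert_allclose(out.A, A, rtol=1e-9)

    def test_constant_area_identity(self):
        t = np.arange(200, dtype=float)
        s = WaveformSeries(t=t, U=np.zeros(200), A=np.full(200, 650.0), dt_native=1.0)
        out = smooth_area(s)
        np.testing.assert_allclose(out.A, 650.0, rtol=1e-12)

    def test_interior_sample_matches_windowed_polyfit(self):
        rng = np.random.default_rng(3)
        t = np.arange(400, dtype=float)
        A = 600 + 40 * np.sin(t / 80) + rng.normal(0, 2.0, 400)
        s = WaveformSeries(t=t, U=np.zeros(400), A=A, dt_native=1.0)
        out = smooth_area(s, poly_order=3, window_samples=101)
        for i in (60, 199, 320):
            lo = i - 50
            window_t = t[lo : lo + 101]
            coeffs = np.polyfit(window_t - t[i], A[lo : lo + 101], 3)
            assert out.A[i] == pytest.approx(coeffs[-1], rel=1e-9)

    def test_even_window_rejected(self):
        t = np.arange(200, dtype=float)
        s = WaveformSeries(t=t, U=np.zeros(200), A=np.full(200, 500.0), dt_native=1.0)
        with pytest.raises(ValidationError, match="odd"):
            smooth_area(s, window_samples=100)

    def test_short_series_window_shrinks_and_is_recorded(self):
        t = np.arange(51, dtype=float)
        s = WaveformSeries(t=t, U=np.zeros(51), A=500 + t, dt_native=1.0)
        out = smooth_area(s, window_samples=101)
        assert out.meta["sg_window_used"] == 51

    def test_velocity_untouched_by_default(self):
        rng = np.random.default_rng(1)
        t = np.arange(150, dtype=float)
        U = rng.normal(0, 1, 150)
        s = WaveformSeries(t=t, U=U, A=np.full(150, 500.0), dt_native=1.0)
        out = smooth_area(s)
        np.testing.assert_array_equal(out.U, U)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.1, 3, allow_nan=False),
        beta=st.floats(0.1, 3, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_filter_linearity(self, alpha, beta, seed):
        """SG(alpha*A1 + beta*A2) == alpha*SG(A1) + beta*SG(A2)."""
        rng = np.random.default_rng(seed)
        t = np.arange(160, dtype=float)
        A1 = 500 + rng.normal(0, 5, 160)
        A2 = 700 + 50 * np.sin(t / 40) + rng.normal(0, 5, 160)

        def sg(a):
            s = WaveformSeries(t=t, U=np.zeros(160), A=a, dt_native=1.0)
            return smooth_area(s, window_samples=41).A

        lhs = sg(alpha * A1 + beta * A2)
        rhs = alpha * sg(A1) + beta * sg(A2)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


class TestFootDetection:
    def test_ramp_foot_below_threshold(self, ramp_series):
        foot = detect_systolic_foot(ramp_series)
        thresh = 0.05 * 1.0
        assert ramp_series.U[foot.index] <= thresh
        assert ramp_series.U[foot.index + 1] > thresh

    def test_constant_offset_invariance(self, ramp_series):
        from dataclasses import replace

        foot0 = detect_systolic_foot(ramp_series)
        shifted = replace(ramp_series, U=ramp_series.U + 0.37)
        assert detect_systolic_foot(shifted).index == foot0.index

    def test_flat_signal_raises(self):
        t = np.arange(50, dtype=float)
        s = WaveformSeries(t=t, U=np.full(50, 0.2), A=np.full(50, 500.0), dt_native=1.0)
        with pytest.raises(DetectionError):
            detect_systolic_foot(s)

    def test_foot_precedes_peak(self, quiet_forward_series):
        series, _ = quiet_forward_series
        foot = detect_systolic_foot(resample_uniform(series))
        r = resample_uniform(series)
        assert 0 <= foot.index < int(np.argmax(r.U))

    def test_monte_carlo_foot_stability_under_noise(self):
        """Noisy detections stay within 5 ms of the noise-free foot >=95/100."""
        from dataclasses import replace as dreplace

        from awia.synthetic import SyntheticSpec, generate

        clean_spec = SyntheticSpec(noise_sd_U=0.0, noise_sd_A=0.0)
        clean, _ = generate(clean_spec)
        ref = detect_systolic_foot(resample_uniform(clean))
        t_ref = resample_uniform(clean).t[ref.index]
        hits = 0
        for seed in range(100):
            spec = SyntheticSpec(noise_sd_U=0.005, noise_sd_A=0.0, seed=seed)
            series, _ = generate(spec)
            r = resample_uniform(series)
            foot = detect_systolic_foot(r)
            if abs(r.t[foot.index] - t_ref) <= 5.0:
                hits += 1
        assert hits >= 95
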