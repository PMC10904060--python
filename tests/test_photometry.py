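"""Unit and property tests for the photometry processing chain."""

import numpy as np
import pytest
from conftest import make_dff, naive_hysteresis_scan

from mitoscope.errors import ValidationError
from mitoscope.photometry import (
    DetectorParams,
    RawPhotometry,
    bin_decimate,
    compute_dff,
    compute_mad,
    correct_motion,
    detect_events,
    event_frequency,
    fit_baseline,
    preprocess_session,
    relative_frequency,
)
from mitoscope.synthetic import TraceSpec, gen_photometry_trace


class TestFitBaseline:
    def test_linear_drift_flattened(self):
        """A pure linear ramp collapses to a constant within 1 % of its mean."""
        t = np.arange(30000) / 50.0
        y = 100.0 + 0.02 * t
        flat, base = fit_baseline(y, "asls")
        assert np.ptp(flat) < 0.01 * flat.mean()
        assert flat.mean() == pytest.approx(y.mean(), rel=1e-9)

    def test_polynomial_method_flattens_drift(self):
        t = np.arange(3000) / 50.0
        y = 50.0 + 0.5 * t - 0.004 * t**2
        flat, _ = fit_baseline(y, "polynomial")
        assert np.ptp(flat) < 0.01 * flat.mean()

    def test_flat_input_identity(self):
        y = np.full(2000, 42.0)
        flat, base = fit_baseline(y)
        np.testing.assert_allclose(flat, y, rtol=1e-6)

    def test_zero_drift_noisy_trace_nearly_unchanged(self, rng):
        y = 100.0 + rng.normal(0, 0.5, 20000)
        flat, _ = fit_baseline(y)
        # the fitted baseline wanders much less than the noise SD (0.5)
        assert np.abs(flat - y).max() < 0.15

    def test_transient_amplitudes_preserved(self):
        """Drift removal keeps transient peaks within 5 % of the drift-free twin."""
        spec = dict(duration_s=400.0, event_rate_hz=0.05, noise_sd=0.0, amplitude=0.3, seed=7)
        raw_drift, truth = gen_photometry_trace(TraceSpec(**spec))
        raw_flat, _ = gen_photometry_trace(
            TraceSpec(**spec, drift_slope=0.0, drift_sine_amp=0.0)
        )
        assert truth.n_events > 0
        flat, _ = fit_baseline(raw_drift.ch_signal, sampling_rate_hz=50.0)
        for onset in truth.onset_times_s:
            i = int(onset * 50)
            sl = slice(i, min(i + 50, flat.size))
            peak = flat[sl].max() - np.median(flat)
            peak_ref = raw_flat.ch_signal[sl].max() - np.median(raw_flat.ch_signal)
            assert peak == pytest.approx(peak_ref, rel=0.05)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            fit_baseline(np.array([1.0, np.nan, 2.0] * 300))

    def test_too_short_rejected_when_rate_known(self):
        with pytest.raises(ValidationError, match="10 s"):
            fit_baseline(np.ones(100) + np.arange(100), sampling_rate_hz=50.0)


class TestCorrectMotion:
    def test_shared_artifact_suppressed(self):
        raw, _ = gen_photometry_trace(
            TraceSpec(
                duration_s=300.0,
                event_rate_hz=0.0,
                motion_amp=5.0,
                motion_rate_hz=0.05,
                gain_410=1.0,
                noise_sd=0.01,
                drift_slope=0.0,
                drift_sine_amp=0.0,
                seed=11,
            )
        )
        before = np.ptp(raw.ch_signal)
        corrected = correct_motion(raw)
        after = np.ptp(corrected.ch_signal)
        assert before > 4.0  # the artifact is actually present
        assert after < 0.1 * before

    def test_uncorrelated_reference_leaves_signal(self, rng):
        n = 10000
        t = np.arange(n) / 50.0
        sig = 100.0 + rng.normal(0, 0.5, n)
        ref = 50.0 + rng.normal(0, 0.5, n)
        corrected = correct_motion(RawPhotometry(t, sig, ref, 50.0))
        assert np.abs(corrected.ch_signal - sig).std() < 0.05

    def test_constant_reference_warns_and_skips(self):
        n = 1000
        t = np.arange(n) / 50.0
        sig = 100.0 + np.sin(t)
        raw = RawPhotometry(t, sig, np.full(n, 30.0), 50.0)
        with pytest.warns(RuntimeWarning, match="constant"):
            out = correct_motion(raw)
        np.testing.assert_array_equal(out.ch_signal, sig)

    def test_no_artifact_correction_keeps_event_count(self):
        """With no shared artifact, regression correction must not change events."""
        raw, _ = gen_photometry_trace(
            TraceSpec(duration_s=300.0, event_rate_hz=0.1, motion_amp=0.0, seed=5)
        )
        base_raw, _ = gen_photometry_trace(
            TraceSpec(duration_s=300.0, event_rate_hz=0.1, motion_amp=0.0, seed=6)
        )
        base_dff = preprocess_session(base_raw)

        def chain(r, correct):
            flat_sig, _ = fit_baseline(r.ch_signal, sampling_rate_hz=50.0)
            flat_ref, _ = fit_baseline(r.ch_reference, sampling_rate_hz=50.0)
            rp = RawPhotometry(r.time_s, flat_sig, flat_ref, 50.0)
            if correct:
                rp = correct_motion(rp)
            return bin_decimate(compute_dff(rp.ch_signal, rp.time_s, 50.0), 4.0)

        n_corr = detect_events(chain(raw, True), base_dff).n_events
        n_raw = detect_events(chain(raw, False), base_dff).n_events
        assert n_corr == n_raw


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        d = compute_dff(np.full(100, 7.0))
        np.testing.assert_allclose(d.dff, 0.0, atol=1e-15)

    @pytest.mark.parametrize("gain", [0.5, 3.0, 1e4])
    def test_scale_invariance(self, rng, gain):
        y = 100.0 + rng.normal(0, 1, 5000)
        np.testing.assert_allclose(
            compute_dff(y).dff, compute_dff(gain * y).dff, atol=1e-12
        )

    def test_sinusoidal_identity(self):
        """F = mu * (1 + 0.2 sin) gives ΔF/F = 0.2 sin exactly."""
        t = np.linspace(0, 4 * np.pi, 10000)
        mod = 0.2 * np.sin(t)
        mod -= mod.mean()  # exact zero-mean modulation
        d = compute_dff(50.0 * (1.0 + mod))
        np.testing.assert_allclose(d.dff, mod, atol=1e-12)

    def test_mean_zero(self, rng):
        d = compute_dff(10.0 + rng.normal(0, 1, 1000))
        assert abs(d.dff.mean()) < 1e-12

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            compute_dff(np.array([-1.0, -2.0, 0.5]))


class TestComputeMad:
    @pytest.mark.parametrize(
        "x,expected",
        [([1, 1, 1], 0.0), ([1, 2, 3, 4, 5], 1.0), ([0, 0, 1, 1], 0.5)],
    )
    def test_by_definition(self, x, expected):
        assert compute_mad(np.array(x, dtype=float)) == expected

    def test_gaussian_quantile(self, rng):
        """Unscaled MAD of N(0,1) approaches the 0.6745 quantile."""
        x = rng.normal(0, 1, 100_000)
        assert compute_mad(x) == pytest.approx(0.674489, rel=0.02)
        assert compute_mad(x, consistency_scaled=True) == pytest.approx(1.0, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_mad(np.array([]))


class TestDetectEvents:
    def _baseline(self):
        # MAD of repeating [-1, 0, 1] is 1 -> threshold 4, rearm 3.6
        return make_dff(np.tile([-1.0, 0.0, 1.0], 400))

    def test_zero_signal_no_events(self):
        ev = detect_events(make_dff(np.zeros(1000)), self._baseline())
        assert ev.n_events == 0
        assert ev.threshold_used == 4.0

    def test_isolated_transients_counted_with_onsets(self):
        x = np.zeros(3000)
        truth = [200, 800, 1400, 2000, 2600]
        for i in truth:
            x[i : i + 25] += 10.0 * np.exp(-np.arange(25) / 6.0)
        ev = detect_events(make_dff(x), self._baseline())
        assert ev.n_events == 5
        np.testing.assert_allclose(ev.onset_times_s, np.array(truth) / 50.0, atol=1 / 50.0)
        assert np.all(ev.peak_dff >= ev.threshold_used)

    @pytest.mark.parametrize("trough_frac,expected", [(0.95, 1), (0.85, 2)])
    def test_doublet_hysteresis(self, trough_frac, expected):
        """Trough above the re-arm level merges a doublet; below it splits."""
        baseline = self._baseline()
        T = 4.0
        x = np.zeros(400)
        x[100:110] = 1.5 * T
        x[110:120] = trough_frac * T
        x[120:130] = 1.5 * T
        ev = detect_events(make_dff(x), baseline)
        assert ev.n_events == expected

    def test_threshold_tie_counts_as_crossing(self):
        x = np.zeros(200)
        x[50:55] = 4.0  # exactly T
        ev = detect_events(make_dff(x), self._baseline())
        assert ev.n_events == 1

    def test_flat_baseline_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            detect_events(make_dff(np.ones(600)), make_dff(np.zeros(600)))

    def test_short_baseline_rejected(self):
        with pytest.raises(ValidationError, match="10 s"):
            detect_events(make_dff(np.zeros(600)), make_dff(np.tile([-1.0, 1.0], 50)))

    def test_matches_naive_scan_on_noise(self, rng):
        base = make_dff(rng.normal(0, 1, 2000))
        x = rng.normal(0, 2, 5000)
        dff = make_dff(x)
        ev = detect_events(dff, base)
        T = ev.threshold_used
        onsets, peaks = naive_hysteresis_scan(x, T, 0.9 * T)
        np.testing.assert_array_equal(ev.onset_times_s, np.array(onsets) / 50.0)
        np.testing.assert_array_equal(ev.peak_times_s, np.array(peaks) / 50.0)

    def test_event_count_monotone_in_k(self, rng):
        base = make_dff(rng.normal(0, 1, 2000))
        x = rng.normal(0, 3, 4000)
        counts = [
            detect_events(make_dff(x), base, DetectorParams(mad_multiplier=k)).n_events
            for k in [1.0, 2.0, 4.0, 8.0]
        ]
        assert counts == sorted(counts, reverse=True)


class TestFrequencies:
    def test_arithmetic(self):
        ev = detect_events(make_dff(np.zeros(600)), make_dff(np.tile([-1.0, 0, 1.0], 400)))
        assert event_frequency(ev, 600.0) == 0.0

    def test_relative_and_percent(self):
        base = make_dff(np.tile([-1.0, 0, 1.0], 400))
        x1 = np.zeros(3000)
        x2 = np.zeros(3000)
        for i in range(0, 3000, 300):
            x1[i : i + 5] = 10.0
        for i in range(0, 3000, 600):
            x2[i : i + 5] = 10.0
        e1 = detect_events(make_dff(x1), base)
        e2 = detect_events(make_dff(x2), base)
        comp = relative_frequency(e1, 60.0, e2, 60.0)
        assert comp.defined
        assert comp.relative_frequency == pytest.approx(0.5)
        assert comp.relative_percent == pytest.approx(50.0)

    def test_zero_baseline_flagged_not_raised(self):
        base = make_dff(np.tile([-1.0, 0, 1.0], 400))
        empty = detect_events(make_dff(np.zeros(1000)), base)
        some = detect_events(make_dff(np.r_[np.zeros(500), 10.0, np.zeros(499)]), base)
        comp = relative_frequency(empty, 20.0, some, 20.0)
        assert not comp.defined
        assert np.isnan(comp.relative_frequency)


class TestBinDecimate:
    def test_bin_means(self):
        d = make_dff(np.arange(100, dtype=float))
        out = bin_decimate(d, target_hz=5.0)  # 10-sample bins at 50 Hz
        np.testing.assert_allclose(out.dff, np.arange(4.5, 100, 10.0))
        assert out.sampling_rate_hz == pytest.approx(5.0)

    def test_piecewise_constant_preserved(self):
        x = np.repeat([0.0, 1.0, 0.0, 2.0], 25)
        out = bin_decimate(make_dff(x), target_hz=2.0)  # 25-sample bins
        np.testing.assert_allclose(out.dff, [0.0, 1.0, 0.0, 2.0])


class TestRawPhotometryValidation:
    def test_mismatched_lengths(self):
        with pytest.raises(ValidationError):
            RawPhotometry(np.arange(5) / 50, np.ones(5), np.ones(4), 50.0)

    def test_nonuniform_time(self):
        t = np.array([0.0, 0.02, 0.05, 0.06])
        with pytest.raises(ValidationError, match="constant"):
            RawPhotometry(t, np.ones(4), np.ones(4), 50.0)
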