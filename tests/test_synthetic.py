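"""Tests of the synthetic-data generators: determinism, statistical laws,
and round trips through the analysis operations they are meant to exercise."""

import numpy as np
import pytest

from mitoscope.errors import GenerationError, ParameterError
from mitoscope.morphometry import ScaleCalibration, measure_image, segment_mitochondria
from mitoscope.photometry import compute_dff
from mitoscope.ratiometric import stim_dff
from mitoscope.synthetic import (
    ImageSpec,
    KeimaSpec,
    StimSpec,
    TraceSpec,
    gen_dendrite_image,
    gen_keima_trace,
    gen_photometry_trace,
    gen_stim_trace,
    render_capsule,
    transient_kernel,
)


class TestPhotometryGenerator:
    def test_degenerate_spec_constant_channels(self):
        spec = TraceSpec(
            duration_s=20.0,
            event_rate_hz=0.0,
            noise_sd=0.0,
            motion_amp=0.0,
            drift_slope=0.0,
            drift_sine_amp=0.0,
        )
        raw, truth = gen_photometry_trace(spec)
        np.testing.assert_array_equal(raw.ch_signal, spec.baseline_level)
        np.testing.assert_array_equal(raw.ch_reference, spec.baseline_level)
        assert truth.n_events == 0

    def test_determinism_same_seed(self):
        spec = TraceSpec(duration_s=600.0, event_rate_hz=0.1, seed=1)
        raw1, t1 = gen_photometry_trace(spec)
        raw2, t2 = gen_photometry_trace(spec)
        np.testing.assert_array_equal(raw1.ch_signal, raw2.ch_signal)
        np.testing.assert_array_equal(raw1.ch_reference, raw2.ch_reference)
        np.testing.assert_array_equal(t1.onset_times_s, t2.onset_times_s)
        # Poisson(60) count within a plausible band
        assert 25 <= t1.n_events <= 100

    def test_event_count_law(self):
        """Mean event count over many seeds within 3 SE of rate x duration."""
        rate, dur, n_seeds = 0.2, 120.0, 200
        counts = [
            gen_photometry_trace(
                TraceSpec(duration_s=dur, event_rate_hz=rate, noise_sd=0.0, seed=s)
            )[1].n_events
            for s in range(n_seeds)
        ]
        expected = rate * dur
        se = np.sqrt(expected / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_amplitude_round_trip_through_dff(self):
        """Noise-free kernel peak survives ΔF/F within 2 % of the nominal value."""
        spec = TraceSpec(
            duration_s=600.0,
            event_rate_hz=0.005,
            amplitude=0.5,
            noise_sd=0.0,
            drift_slope=0.0,
            drift_sine_amp=0.0,
            seed=3,
        )
        raw, truth = gen_photometry_trace(spec)
        assert truth.n_events > 0
        dff = compute_dff(raw.ch_signal, raw.time_s, 50.0)
        assert dff.dff.max() == pytest.approx(0.5, rel=0.02)

    def test_invalid_spec_names_field(self):
        with pytest.raises(ParameterError, match="decay_tau_s"):
            gen_photometry_trace(TraceSpec(rise_tau_s=0.5, decay_tau_s=0.1))
        with pytest.raises(ParameterError, match="event_rate_hz"):
            gen_photometry_trace(TraceSpec(event_rate_hz=-1.0))

    def test_refractory_enforces_min_gap(self):
        spec = TraceSpec(duration_s=600.0, event_rate_hz=0.5, refractory=True, seed=2)
        _, truth = gen_photometry_trace(spec)
        gaps = np.diff(truth.onset_times_s)
        assert np.all(gaps >= 3.0 * spec.decay_tau_s)

    def test_kernel_peak_normalized(self):
        k = transient_kernel(0.05, 0.3, 50.0)
        assert k.max() == pytest.approx(1.0)
        assert k[0] == 0.0


class TestKeimaGenerator:
    def test_equal_channels_unit_ratio(self):
        # choose the acidic fraction that equalizes the two expected levels
        # (1-a)*B = a*B + leak*(1-a)*B  =>  a = (1-leak)/(2-leak)
        leak = 0.1
        a = (1 - leak) / (2 - leak)
        trace = gen_keima_trace(KeimaSpec(acidic_fraction=a, leak_fraction=leak, noise_sd=0.0))
        np.testing.assert_allclose(trace.ex586 / trace.ex440, 1.0, atol=1e-12)

    def test_ratio_monotone_in_acidic_fraction(self):
        ratios = []
        for a in [0.1, 0.3, 0.5]:
            tr = gen_keima_trace(KeimaSpec(acidic_fraction=a, noise_sd=0.0, seed=1))
            ratios.append((tr.ex586 / tr.ex440).mean())
        assert ratios[0] < ratios[1] < ratios[2]

    def test_noise_free_ratio_constant(self):
        tr = gen_keima_trace(KeimaSpec(acidic_fraction=0.2, noise_sd=0.0))
        r = tr.ex586 / tr.ex440
        assert np.ptp(r) == 0.0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ParameterError, match="acidic_fraction"):
            gen_keima_trace(KeimaSpec(acidic_fraction=1.5))


class TestStimGenerator:
    def test_null_response_mean_within_noise(self):
        spec = StimSpec(response_amplitude=0.0, noise_sd=0.5, seed=4)
        summary = stim_dff(gen_stim_trace(spec))
        post = summary.time_s >= spec.injection_time_s
        n_post = post.sum()
        noise_se = (spec.noise_sd / spec.baseline_level) / np.sqrt(n_post)
        assert abs(summary.dff_t[post].mean()) < 3 * noise_se

    def test_noise_free_peak_equals_amplitude(self):
        spec = StimSpec(response_amplitude=0.3, noise_sd=0.0, seed=0)
        summary = stim_dff(gen_stim_trace(spec), convention="paper")
        assert summary.peak_dff == pytest.approx(0.3, abs=1e-9)

    def test_two_seeds_same_underlying_shape(self):
        a = gen_stim_trace(StimSpec(seed=1))
        b = gen_stim_trace(StimSpec(seed=2))
        assert not np.array_equal(a.F, b.F)
        a0 = gen_stim_trace(StimSpec(seed=1, noise_sd=0.0))
        b0 = gen_stim_trace(StimSpec(seed=2, noise_sd=0.0))
        np.testing.assert_array_equal(a0.F, b0.F)

    def test_injection_before_prestim_rejected(self):
        with pytest.raises(ParameterError, match="injection_time_s"):
            gen_stim_trace(StimSpec(injection_time_s=50.0, prestim_s=100.0))


class TestDendriteImageGenerator:
    def test_empty_image(self):
        stack, gt, roi = gen_dendrite_image(ImageSpec(n_mito=0, seed=0))
        assert len(gt) == 0
        assert segment_mitochondria(stack[0]).max() == 0

    def test_single_capsule_round_trip(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        render_capsule(img, (16.0, 16.0), 10.0, 4.0, 0.0, 200)
        labels = segment_mitochondria(img)
        assert labels.max() == 1
        from mitoscope.morphometry import measure_object

        obj = measure_object(labels == 1, ScaleCalibration(50.0))  # 1 um/px
        assert obj.length_um == pytest.approx(10.0, abs=1.0)

    def test_determinism(self):
        s1, g1, r1 = gen_dendrite_image(ImageSpec(seed=9))
        s2, g2, r2 = gen_dendrite_image(ImageSpec(seed=9))
        np.testing.assert_array_equal(s1, s2)
        assert g1.equals(g2)

    def test_label_fidelity_every_object_segmentable(self):
        """Each ground-truth object yields a gate-passing component at its centroid."""
        for seed in range(6):
            stack, gt, roi = gen_dendrite_image(ImageSpec(seed=seed))
            table = measure_image(stack[0], roi=roi)
            assert len(table) == len(gt)
            for _, g in gt.iterrows():
                d = np.hypot(
                    table.centroid_row - g.centroid_row,
                    table.centroid_col - g.centroid_col,
                )
                assert d.min() < 3.0

    def test_class_assignment_matches_ground_truth(self):
        hits = total = 0
        for seed in range(6):
            stack, gt, roi = gen_dendrite_image(ImageSpec(seed=seed))
            table = measure_image(stack[0], roi=roi)
            for _, g in gt.iterrows():
                d = np.hypot(
                    table.centroid_row - g.centroid_row,
                    table.centroid_col - g.centroid_col,
                )
                j = d.idxmin()
                hits += table.loc[j, "class"] == g.dendrite_class
                total += 1
        assert hits / total >= 0.95

    def test_overcrowded_image_reports_placed_count(self):
        with pytest.raises(GenerationError, match="placed"):
            gen_dendrite_image(ImageSpec(n_mito=500, seed=0, max_tries_per_object=20))

    def test_foreground_within_segmentation_window(self):
        stack, gt, _ = gen_dendrite_image(ImageSpec(seed=3))
        fg = stack[0][stack[0] >= 162]
        assert fg.size > 0
        assert fg.max() <= 255
        bg = stack[0][stack[0] < 162]
        assert bg.max() <= 161
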