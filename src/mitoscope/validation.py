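"""Validation experiments on synthetic ground truth.

Each function runs one of the package's headline validation studies — the
kind of checks a methods section reports: detector equivalence against a
naive scan, hysteresis semantics on constructed waveforms, end-to-end event
rate recovery, motion-artifact suppression, scale invariance, segmentation
gate exactness, calibration, capsule shape recovery, KS power for
fragmentation detection, and the deterministic score formulas.

All randomness is controlled by an explicit seed; problem sizes default to
the study conditions used in the test suite.
"""

from __future__ import annotations

import numpy as np

from .behavior import AnalgesiaTrial, ChamberSession, WithdrawalRecord, cpa_score, mpe_percent, weight_loss_percent
from .morphometry import (
    ScaleCalibration,
    SegmentationParams,
    ks_two_sample,
    measure_image,
    measure_object,
    segment_mitochondria,
)
from .photometry import (
    DffTrace,
    compute_dff,
    detect_events,
    preprocess_session,
)
from .ratiometric import mitophagy_index
from .synthetic import (
    ImageSpec,
    KeimaSpec,
    TraceSpec,
    gen_dendrite_image,
    gen_keima_trace,
    gen_photometry_trace,
    render_capsule,
)

__all__ = [
    "naive_hysteresis_onsets",
    "detector_oracle_agreement",
    "doublet_event_count",
    "rate_recovery",
    "artifact_suppression",
    "scale_invariance",
    "gate_exactness",
    "calibration_check",
    "capsule_recovery",
    "cohort_lengths",
    "ks_power",
    "ks_oracle_agreement",
    "mitophagy_checks",
    "score_checks",
]


def naive_hysteresis_onsets(x: np.ndarray, threshold: float, rearm: float) -> list[int]:
    """Reference sample-by-sample hysteresis scan (independent of detect_events)."""
    onsets: list[int] = []
    armed = True
    for i, v in enumerate(x):
        if armed and v >= threshold:
            onsets.append(i)
            armed = False
        elif not armed and v < rearm:
            armed = True
    return onsets


def detector_oracle_agreement(
    n_traces: int = 100, duration_s: float = 600.0, seed: int = 0
) -> dict:
    """Fraction of seeded synthetic traces on which detect_events onsets
    exactly equal the naive hysteresis scan."""
    agree = 0
    total_events = 0
    for i in range(n_traces):
        raw, _ = gen_photometry_trace(
            TraceSpec(duration_s=duration_s, event_rate_hz=0.1, seed=seed + i)
        )
        base_raw, _ = gen_photometry_trace(
            TraceSpec(duration_s=duration_s, event_rate_hz=0.1, seed=seed + 50_000 + i)
        )
        dff = compute_dff(raw.ch_signal, raw.time_s, raw.sampling_rate_hz)
        base = compute_dff(base_raw.ch_signal, base_raw.time_s, base_raw.sampling_rate_hz)
        events = detect_events(dff, base)
        T = events.threshold_used
        oracle = naive_hysteresis_onsets(dff.dff, T, 0.9 * T)
        onsets_idx = np.round(events.onset_times_s * raw.sampling_rate_hz).astype(int)
        agree += list(onsets_idx) == oracle
        total_events += events.n_events
    return {"agreement_fraction": agree / n_traces, "n_traces": n_traces, "n_events": total_events}


def _mad_one_baseline() -> DffTrace:
    # repeating [-1, 0, 1] has MAD exactly 1 -> threshold 4, re-arm 3.6
    x = np.tile([-1.0, 0.0, 1.0], 400)
    return DffTrace(np.arange(x.size) / 50.0, x, 1.0, 50.0)


def doublet_event_count(trough_fraction: float) -> int:
    """Events detected for a doublet whose inter-peak trough sits at
    ``trough_fraction`` of the 4xMAD threshold (re-arm level is 0.9)."""
    baseline = _mad_one_baseline()
    T = 4.0
    x = np.zeros(400)
    x[100:110] = 1.5 * T
    x[110:120] = trough_fraction * T
    x[120:130] = 1.5 * T
    dff = DffTrace(np.arange(x.size) / 50.0, x, 1.0, 50.0)
    return detect_events(dff, baseline).n_events


def rate_recovery(
    rates_hz: tuple[float, ...] = (0.05, 0.2),
    n_seeds: int = 50,
    duration_s: float = 600.0,
    seed: int = 0,
) -> dict:
    """End-to-end recovery of the generator event rate.

    For each seed and rate, a baseline and a test session are generated with
    the same spec (amplitude 8x the ΔF/F noise SD), pushed through the full
    chain (AsLS flatten, isosbestic regression, ΔF/F, 4 Hz binning,
    hysteresis detection with the threshold from the baseline session), and
    the recovered rate is compared with the true event count of the test
    session. Returns the median |relative error| per rate.
    """
    out = {}
    for rate in rates_hz:
        errs = []
        for i in range(n_seeds):
            base_raw, _ = gen_photometry_trace(
                TraceSpec(duration_s=duration_s, event_rate_hz=rate, seed=seed + 2 * i)
            )
            test_raw, truth = gen_photometry_trace(
                TraceSpec(duration_s=duration_s, event_rate_hz=rate, seed=seed + 2 * i + 1)
            )
            if truth.n_events == 0:
                continue
            base_dff = preprocess_session(base_raw)
            test_dff = preprocess_session(test_raw)
            events = detect_events(test_dff, base_dff)
            errs.append(abs(events.n_events - truth.n_events) / truth.n_events)
        out[rate] = float(np.median(errs))
    return out


def artifact_suppression(seed: int = 0) -> dict:
    """Shared square-pulse artifact: attenuation by isosbestic regression and
    the event count on an artifact-only (event-free) trace.

    The regression slope is fitted on the noisy recording; the attenuation is
    then measured on the noise-free twin (same seed, so the identical pulse
    train), which isolates the artifact component from the acquisition noise.
    """
    conditions = dict(
        duration_s=600.0,
        event_rate_hz=0.0,
        motion_amp=5.0,
        motion_rate_hz=0.05,
        gain_410=1.0,
        drift_slope=0.0,
        drift_sine_amp=0.0,
        seed=seed,
    )
    raw, _ = gen_photometry_trace(TraceSpec(noise_sd=0.05, **conditions))
    twin, _ = gen_photometry_trace(TraceSpec(noise_sd=0.0, **conditions))
    a, b = np.polyfit(raw.ch_reference, raw.ch_signal, 1)
    artifact = twin.ch_signal - twin.ch_signal.min()  # pure pulse train
    residual = twin.ch_signal - (a * twin.ch_reference + b)
    before = np.ptp(artifact)
    after = np.ptp(residual)
    base_raw, _ = gen_photometry_trace(
        TraceSpec(duration_s=600.0, event_rate_hz=0.1, seed=seed + 1)
    )
    events = detect_events(preprocess_session(raw), preprocess_session(base_raw))
    return {
        "attenuation_fraction": 1.0 - after / before,
        "artifact_only_events": events.n_events,
    }


def scale_invariance(gain: float = 3.7, seed: int = 0) -> dict:
    """Effect of a common positive gain on ΔF/F and the detected EventSet."""
    from .photometry import RawPhotometry

    raw, _ = gen_photometry_trace(TraceSpec(duration_s=300.0, event_rate_hz=0.1, seed=seed))
    base_raw, _ = gen_photometry_trace(
        TraceSpec(duration_s=300.0, event_rate_hz=0.1, seed=seed + 1)
    )

    def chain(r, g):
        scaled = RawPhotometry(
            r.time_s, g * r.ch_signal, g * r.ch_reference, r.sampling_rate_hz
        )
        return preprocess_session(scaled)

    dff1, dff2 = chain(raw, 1.0), chain(raw, gain)
    base1, base2 = chain(base_raw, 1.0), chain(base_raw, gain)
    ev1 = detect_events(dff1, base1)
    ev2 = detect_events(dff2, base2)
    max_dff_diff = float(np.abs(dff1.dff - dff2.dff).max())
    onsets_equal = np.array_equal(ev1.onset_times_s, ev2.onset_times_s)
    return {
        "max_dff_diff": max_dff_diff,
        "onsets_equal": bool(onsets_equal),
        "n_events": ev1.n_events,
    }


def gate_exactness() -> dict:
    """Inclusive segmentation bounds: 4/5/200/201-px areas, 161/162 levels."""
    results = {}
    for area in (4, 5, 200, 201):
        img = np.full((40, 260), 40, dtype=np.uint8)
        img[10, 10 : 10 + area] = 200
        results[f"area_{area}_kept"] = bool(segment_mitochondria(img).max() == 1)
    for level in (161, 162):
        img = np.full((40, 40), 40, dtype=np.uint8)
        img[10:14, 10:20] = level
        results[f"intensity_{level}_kept"] = bool(segment_mitochondria(img).max() == 1)
    return results


def calibration_check() -> dict:
    """169-px segment -> 50 um; calibration doubling halves/quarters metrics."""
    img = np.full((32, 200), 40, dtype=np.uint8)
    img[15, 10:179] = 200
    labels = segment_mitochondria(img, SegmentationParams(max_area_px=500))
    obj1 = measure_object(labels == 1, ScaleCalibration(169.0))
    obj2 = measure_object(labels == 1, ScaleCalibration(338.0))
    return {
        "segment_length_um": obj1.length_um,
        "length_ratio_on_double_calibration": obj2.length_um / obj1.length_um,
        "area_ratio_on_double_calibration": obj2.area_um2 / obj1.area_um2,
    }


def capsule_recovery(
    rotations_deg: tuple[float, ...] = (0.0, 30.0, 45.0, 90.0),
    n_instances: int = 200,
    length_um: float = 3.0,
    aspect_ratio: float = 4.0,
    seed: int = 0,
) -> dict:
    """Cohort-mean recovery of capsule length and aspect ratio per rotation.

    Instances are rendered with random sub-pixel placement; per-instance AR
    of such thin objects (width ~2.5 px at the default calibration) is
    quantized by the binary grid, so the population mean is the meaningful
    recovery statistic.
    """
    cal = ScaleCalibration(169.0)
    length_px = length_um / cal.um_per_px
    rng = np.random.default_rng(seed)
    out = {}
    for angle in rotations_deg:
        lengths, ars = [], []
        for _ in range(n_instances):
            img = np.full((48, 48), 40, dtype=np.uint8)
            c = (24 + rng.uniform(-0.5, 0.5), 24 + rng.uniform(-0.5, 0.5))
            render_capsule(img, c, length_px, length_px / aspect_ratio, angle, 200)
            obj = measure_object(img >= 162, cal)
            lengths.append(obj.length_um)
            ars.append(obj.aspect_ratio)
        out[angle] = {
            "mean_length_um": float(np.mean(lengths)),
            "mean_aspect_ratio": float(np.mean(ars)),
        }
    return out


def cohort_lengths(
    length_um_mean: float, n_objects: int, seed: int, length_um_sd: float = 0.4
) -> np.ndarray:
    """Measured lengths of a cohort rendered across as many images as needed."""
    lengths: list[float] = []
    img_seed = seed
    while len(lengths) < n_objects:
        stack, _, _ = gen_dendrite_image(
            ImageSpec(
                width_px=420,
                height_px=520,
                n_mito=50,
                length_um_mean=length_um_mean,
                length_um_sd=length_um_sd,
                n_secondary_branches=5,
                secondary_path_um=60.0,
                seed=img_seed,
            )
        )
        table = measure_image(stack[0])
        lengths.extend(table["length_um"].tolist())
        img_seed += 1
    return np.asarray(lengths[:n_objects])


def ks_power(n_runs: int = 50, n_objects: int = 200, seed: int = 0) -> dict:
    """Power and null calibration of the KS fragmentation comparison.

    Power: cohorts with true mean length 1.0 vs 2.0 um, n = 200 measured
    objects each, tested at p < 0.001. Null: a single 2x200 cohort from one
    distribution split at random, checked for p > 0.05.
    """
    rng = np.random.default_rng(seed)
    power_hits = 0
    null_hits = 0
    for i in range(n_runs):
        frag = cohort_lengths(1.0, n_objects, seed=seed + 10_000 + 7 * i)
        ctrl = cohort_lengths(2.0, n_objects, seed=seed + 20_000 + 7 * i, length_um_sd=0.8)
        power_hits += ks_two_sample(frag, ctrl).pvalue < 1e-3
        pool = cohort_lengths(1.5, 2 * n_objects, seed=seed + 30_000 + 7 * i, length_um_sd=0.6)
        perm = rng.permutation(pool)
        null_hits += ks_two_sample(perm[:n_objects], perm[n_objects:]).pvalue > 0.05
    return {
        "power_fraction": power_hits / n_runs,
        "null_fraction": null_hits / n_runs,
        "n_runs": n_runs,
    }


def ks_oracle_agreement(n_trials: int = 100, n: int = 20, seed: int = 0) -> dict:
    """Exact agreement of the KS statistic with a double-loop ECDF supremum."""

    def brute(x, y):
        d = 0.0
        for v in np.concatenate([x, y]):
            d = max(d, abs(np.mean(x <= v) - np.mean(y <= v)))
        return d

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_trials):
        x = rng.normal(0.0, 1.0, n)
        y = rng.normal(0.4, 1.3, n)
        max_diff = max(max_diff, abs(ks_two_sample(x, y).statistic - brute(x, y)))
    return {"max_abs_difference": max_diff, "n_trials": n_trials}


def mitophagy_checks() -> dict:
    """Unit ratio on symmetric channels, gain invariance, and monotonicity of
    the induction in the acidic fraction (noise-free)."""
    leak = 0.1
    a_equal = (1 - leak) / (2 - leak)
    tr = gen_keima_trace(KeimaSpec(acidic_fraction=a_equal, leak_fraction=leak, noise_sd=0.0))
    idx_equal = mitophagy_index(tr, tr)
    base = gen_keima_trace(KeimaSpec(acidic_fraction=0.05, noise_sd=0.0))
    inductions = [
        mitophagy_index(
            gen_keima_trace(KeimaSpec(acidic_fraction=a, noise_sd=0.0)), base
        ).relative_induction_pct
        for a in (0.1, 0.3, 0.5)
    ]
    from .ratiometric import DualExcitationTrace

    g = 13.7
    scaled = DualExcitationTrace(tr.time_s, g * tr.ex440, g * tr.ex586)
    idx_scaled = mitophagy_index(scaled, scaled)
    return {
        "equal_channel_ratio": idx_equal.test_ratio,
        "gain_invariance_error": abs(idx_scaled.test_ratio - idx_equal.test_ratio),
        "inductions_pct": inductions,
        "monotone": bool(inductions[0] < inductions[1] < inductions[2]),
    }


def score_checks() -> dict:
    """The deterministic score formulas on their defining examples."""
    return {
        "mpe_10_60_60": mpe_percent(AnalgesiaTrial(10.0, 60.0, "hotplate", 60.0)),
        "mpe_10_10_60": mpe_percent(AnalgesiaTrial(10.0, 10.0, "hotplate", 60.0)),
        "mpe_10_35_60": mpe_percent(AnalgesiaTrial(10.0, 35.0, "hotplate", 60.0)),
        "cpa_400_700": cpa_score(ChamberSession(400.0, 700.0)),
        "cpa_700_400": cpa_score(ChamberSession(700.0, 400.0)),
        "weight_loss_25_24_pct": weight_loss_percent(WithdrawalRecord(25.0, 24.0)),
    }
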