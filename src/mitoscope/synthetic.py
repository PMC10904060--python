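"""Ground-truth-labeled synthetic data for every analysis stage.

Each generator is deterministic given its spec (which includes the seed) and
returns the ground truth alongside the rendered data, so detection,
ratiometric, and morphometric operations can be validated without any
external recordings.

Emulated structure:

* photometry traces - calcium transients (difference-of-exponentials kernel,
  Poisson onsets) riding on linear + sinusoidal drift, shared square-pulse
  motion artifacts coupled into the 410-nm reference channel with a known
  gain, and white acquisition noise;
* dual-excitation (mt-Keima-like) traces with a controllable acidic fraction;
* stimulus-evoked ramp/plateau/decay responses;
* two-channel dendrite images with capsule-shaped mitochondria drawn from
  controllable length/aspect-ratio distributions and known primary/secondary
  dendrite classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError, ParameterError
from .morphometry import DendriteROI
from .photometry import RawPhotometry
from .ratiometric import DualExcitationTrace, StimResponseTrace

__all__ = [
    "TraceSpec",
    "GroundTruthEvents",
    "KeimaSpec",
    "StimSpec",
    "ImageSpec",
    "transient_kernel",
    "gen_photometry_trace",
    "gen_keima_trace",
    "gen_stim_trace",
    "render_capsule",
    "gen_dendrite_image",
]


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class TraceSpec:
    """Conditions for a two-channel photometry recording.

    Amplitude is in ΔF/F units (fraction of the baseline fluorescence);
    noise, drift and motion amplitudes are in raw-signal units. The default
    transient kinetics (rise τ 0.05 s, decay τ 0.3 s) are representative of
    fast GCaMP variants; the default amplitude is 8x the ΔF/F noise SD.
    """

    duration_s: float = 600.0
    sampling_rate_hz: float = 50.0
    event_rate_hz: float = 0.1
    amplitude: float = 0.04
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.3
    noise_sd: float = 0.5
    drift_slope: float = -0.005
    drift_sine_amp: float = 0.5
    drift_sine_period_s: float = 120.0
    motion_amp: float = 0.0
    motion_rate_hz: float = 0.02
    motion_dur_s: tuple[float, float] = (0.2, 1.0)
    gain_410: float = 1.0
    baseline_level: float = 100.0
    refractory: bool = False
    seed: int = 0

    def validate(self) -> None:
        _require(self.duration_s > 0, "duration_s", "must be > 0")
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz", "must be > 0")
        _require(self.event_rate_hz >= 0, "event_rate_hz", "must be >= 0")
        _require(self.rise_tau_s > 0, "rise_tau_s", "must be > 0")
        _require(
            self.decay_tau_s > self.rise_tau_s,
            "decay_tau_s",
            "must exceed rise_tau_s",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.baseline_level > 0, "baseline_level", "must be > 0")
        _require(self.drift_sine_period_s > 0, "drift_sine_period_s", "must be > 0")


@dataclass
class GroundTruthEvents:
    """True transient onset times of a generated trace."""

    onset_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)

    @property
    def n_events(self) -> int:
        return self.onset_times_s.size


@dataclass(frozen=True)
class KeimaSpec:
    """Conditions for a dual-excitation trace with a known acidic fraction.

    ``acidic_fraction`` is the fraction of the mitochondrial population in the
    acidic (586-excitable, lysosomal) state. A small ``leak_fraction`` of the
    neutral population also excites at 586 nm, so the 586/440 ratio is
    positive at acidic_fraction 0 and strictly increasing in it.
    """

    duration_s: float = 300.0
    sampling_rate_hz: float = 50.0
    acidic_fraction: float = 0.1
    base_440: float = 100.0
    base_586: float = 100.0
    leak_fraction: float = 0.1
    noise_sd: float = 0.5
    drift_slope: float = 0.0
    drift_sine_amp: float = 0.0
    drift_sine_period_s: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        _require(0 <= self.acidic_fraction <= 1, "acidic_fraction", "must lie in [0, 1]")
        _require(self.duration_s > 0, "duration_s", "must be > 0")
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz", "must be > 0")
        _require(self.base_440 > 0, "base_440", "must be > 0")
        _require(self.base_586 > 0, "base_586", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass(frozen=True)
class StimSpec:
    """Conditions for a stimulus-evoked (infusion) response trace.

    ``response_amplitude`` is the target ΔF/F of the plateau under the
    (F - F0)/F convention; the raw plateau level is back-computed so the
    downstream ΔF/F recovers the requested amplitude exactly in the
    noise-free case.
    """

    duration_s: float = 400.0
    sampling_rate_hz: float = 50.0
    injection_time_s: float = 120.0
    prestim_s: float = 100.0
    response_amplitude: float = 0.2
    rise_time_s: float = 10.0
    plateau_s: float = 60.0
    decay_tau_s: float = 60.0
    baseline_level: float = 100.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        _require(self.duration_s > 0, "duration_s", "must be > 0")
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz", "must be > 0")
        _require(
            self.injection_time_s >= self.prestim_s,
            "injection_time_s",
            "must be >= prestim_s so the prestimulus window fits",
        )
        _require(self.response_amplitude < 1, "response_amplitude", "must be < 1")
        _require(self.rise_time_s >= 0, "rise_time_s", "must be >= 0")
        _require(self.decay_tau_s > 0, "decay_tau_s", "must be > 0")
        _require(self.baseline_level > 0, "baseline_level", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass(frozen=True)
class ImageSpec:
    """Conditions for a two-channel dendrite image with capsule mitochondria.

    Mitochondrion lengths are lognormal with the given linear-space mean/SD;
    aspect ratios are normal truncated at 1. Objects are placed on the
    dendrite skeleton (a straight primary path from the soma plus secondary
    branches) without overlap, with hard intensity fill (no anti-aliasing).
    """

    width_px: int = 512
    height_px: int = 512
    n_mito: int = 30
    length_um_mean: float = 2.0
    length_um_sd: float = 0.8
    aspect_ratio_mean: float = 4.0
    aspect_ratio_sd: float = 1.0
    mito_intensity_range: tuple[int, int] = (180, 230)
    background_level: int = 40
    noise_sd: float = 5.0
    px_per_50um: float = 169.0
    soma_xy: tuple[float, float] | None = None  # (row, col); default mid-left
    primary_path_um: float = 50.0
    n_secondary_branches: int = 3
    secondary_path_um: float = 45.0
    dendrite_width_px: float = 3.0
    orientation_jitter_deg: float = 10.0
    clearance_px: float = 2.0
    min_footprint_px: float = 6.5
    max_footprint_px: float = 170.0
    max_tries_per_object: int = 400
    seed: int = 0

    def validate(self) -> None:
        _require(self.width_px > 0 and self.height_px > 0, "width_px/height_px", "must be > 0")
        _require(self.n_mito >= 0, "n_mito", "must be >= 0")
        _require(self.length_um_mean > 0, "length_um_mean", "must be > 0")
        _require(self.length_um_sd > 0, "length_um_sd", "must be > 0")
        _require(self.aspect_ratio_mean >= 1, "aspect_ratio_mean", "must be >= 1")
        lo, hi = self.mito_intensity_range
        _require(
            162 <= lo <= hi <= 255,
            "mito_intensity_range",
            "foreground intensities must lie inside [162, 255]",
        )
        _require(
            0 <= self.background_level < 162,
            "background_level",
            "must be an 8-bit level below the 162 segmentation floor",
        )
        _require(self.px_per_50um > 0, "px_per_50um", "must be > 0")
        _require(self.primary_path_um > 0, "primary_path_um", "must be > 0")
        _require(self.n_secondary_branches >= 0, "n_secondary_branches", "must be >= 0")


def transient_kernel(
    rise_tau_s: float, decay_tau_s: float, sampling_rate_hz: float
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials calcium transient kernel."""
    t = np.arange(0.0, rise_tau_s + 8.0 * decay_tau_s, 1.0 / sampling_rate_hz)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    peak = k.max()
    if peak <= 0:
        raise ParameterError("decay_tau_s: kernel peak is non-positive")
    return k / peak


def _drift(t: np.ndarray, slope: float, sine_amp: float, sine_period_s: float) -> np.ndarray:
    return slope * t + sine_amp * np.sin(2.0 * np.pi * t / sine_period_s)


def _motion_pulses(
    rng: np.random.Generator,
    n: int,
    fs: float,
    duration_s: float,
    amp: float,
    rate_hz: float,
    dur_range: tuple[float, float],
) -> np.ndarray:
    """Sum of random square pulses (shared-artifact model)."""
    motion = np.zeros(n)
    if amp == 0 or rate_hz == 0:
        return motion
    n_pulses = rng.poisson(rate_hz * duration_s)
    starts = rng.uniform(0.0, duration_s, n_pulses)
    durs = rng.uniform(dur_range[0], dur_range[1], n_pulses)
    for s, d in zip(starts, durs):
        i0 = int(s * fs)
        i1 = min(int((s + d) * fs) + 1, n)
        motion[i0:i1] += amp
    return motion


def _poisson_onsets(
    rng: np.random.Generator,
    rate_hz: float,
    duration_s: float,
    min_gap_s: float = 0.0,
) -> np.ndarray:
    n_ev = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, n_ev))
    if min_gap_s > 0 and onsets.size:
        kept = [onsets[0]]
        for t in onsets[1:]:
            if t - kept[-1] >= min_gap_s:
                kept.append(t)
        onsets = np.asarray(kept)
    return onsets


def gen_photometry_trace(spec: TraceSpec) -> tuple[RawPhotometry, GroundTruthEvents]:
    """Generate a two-channel photometry trace plus its true event onsets.

    The 470-nm channel carries baseline + drift + motion + transients +
    noise; the 410-nm reference carries baseline + drift + gain_410 * motion
    + independent noise and no transients. Identical specs (same seed) give
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    drift = _drift(t, spec.drift_slope, spec.drift_sine_amp, spec.drift_sine_period_s)
    motion = _motion_pulses(
        rng, n, fs, spec.duration_s, spec.motion_amp, spec.motion_rate_hz, spec.motion_dur_s
    )
    min_gap = 3.0 * spec.decay_tau_s if spec.refractory else 0.0
    onsets = _poisson_onsets(rng, spec.event_rate_hz, spec.duration_s, min_gap)
    transients = np.zeros(n)
    if onsets.size:
        kernel = transient_kernel(spec.rise_tau_s, spec.decay_tau_s, fs)
        kernel = kernel * spec.amplitude * spec.baseline_level
        for onset in onsets:
            i = int(round(onset * fs))
            if i >= n:
                continue
            seg = kernel[: n - i]
            transients[i : i + seg.size] += seg
    noise_sig = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else np.zeros(n)
    noise_ref = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else np.zeros(n)
    ch470 = spec.baseline_level + drift + motion + transients + noise_sig
    ch410 = spec.baseline_level + drift + spec.gain_410 * motion + noise_ref
    raw = RawPhotometry(t, ch470, ch410, fs)
    return raw, GroundTruthEvents(onsets)


def gen_keima_trace(spec: KeimaSpec) -> DualExcitationTrace:
    """Generate a dual-excitation trace with a known acidic fraction.

    Expected channel levels: ``I440 = (1 - a) * base_440`` and
    ``I586 = a * base_586 + leak * (1 - a) * base_586``; the expected 586/440
    ratio is strictly increasing in the acidic fraction ``a``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    a = spec.acidic_fraction
    level_440 = (1.0 - a) * spec.base_440
    level_586 = a * spec.base_586 + spec.leak_fraction * (1.0 - a) * spec.base_586
    drift = _drift(t, spec.drift_slope, spec.drift_sine_amp, spec.drift_sine_period_s)
    noise_440 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else np.zeros(n)
    noise_586 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else np.zeros(n)
    ex440 = level_440 + drift + noise_440
    ex586 = level_586 + drift + noise_586
    return DualExcitationTrace(t, ex440, ex586)


def gen_stim_trace(spec: StimSpec) -> StimResponseTrace:
    """Generate a flat prestimulus segment followed by a ramp-plateau-decay
    response whose noise-free ΔF/F plateau equals ``response_amplitude``
    under the (F - F0)/F convention."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    f0 = spec.baseline_level
    # plateau raw level such that (F - F0)/F == amplitude
    amp_raw = f0 * spec.response_amplitude / (1.0 - spec.response_amplitude)
    shape = np.zeros(n)
    dt_inj = t - spec.injection_time_s
    if spec.rise_time_s > 0:
        ramp = np.clip(dt_inj / spec.rise_time_s, 0.0, 1.0)
    else:
        ramp = (dt_inj >= 0).astype(float)
    shape = ramp.copy()
    decay_start = spec.rise_time_s + spec.plateau_s
    tail = dt_inj > decay_start
    shape[tail] = np.exp(-(dt_inj[tail] - decay_start) / spec.decay_tau_s)
    shape[dt_inj < 0] = 0.0
    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else np.zeros(n)
    F = f0 + amp_raw * shape + noise
    return StimResponseTrace(t, F, spec.injection_time_s, spec.prestim_s)


def render_capsule(
    img: np.ndarray,
    center_rc: tuple[float, float],
    length_px: float,
    width_px: float,
    angle_deg: float,
    value: int,
) -> None:
    """Hard-fill a rotated capsule (rectangle with semicircular caps).

    A pixel is set to ``value`` when its center lies within ``width_px / 2``
    of the capsule's central segment. No anti-aliasing, so pixel-exact area
    assertions hold downstream.
    """
    cr, cc = center_rc
    r = width_px / 2.0
    half = max(length_px - width_px, 0.0) / 2.0
    th = math.radians(angle_deg)
    uc, ur = math.cos(th), math.sin(th)  # unit vector (col, row)
    pad = int(math.ceil(length_px / 2 + r)) + 1
    r0 = max(int(cr) - pad, 0)
    r1 = min(int(cr) + pad + 1, img.shape[0])
    c0 = max(int(cc) - pad, 0)
    c1 = min(int(cc) + pad + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dr = rows - cr
    dc = cols - cc
    tproj = np.clip(dc * uc + dr * ur, -half, half)
    d2 = (dc - tproj * uc) ** 2 + (dr - tproj * ur) ** 2
    sub = img[r0:r1, c0:c1]
    sub[d2 <= r * r] = value


@dataclass
class _Segment:
    start_rc: np.ndarray
    direction: np.ndarray  # unit (row, col)
    length_px: float
    dendrite_class: str
    arc_offset_px: float  # path distance from soma to segment start


def _build_skeleton(spec: ImageSpec, rng: np.random.Generator) -> list[_Segment]:
    px_per_um = spec.px_per_50um / 50.0
    soma = (
        np.asarray(spec.soma_xy, dtype=float)
        if spec.soma_xy is not None
        else np.array([spec.height_px / 2.0, 8.0])
    )
    primary_len = spec.primary_path_um * px_per_um
    segs = [
        _Segment(soma, np.array([0.0, 1.0]), primary_len, "primary", 0.0)
    ]
    for i in range(spec.n_secondary_branches):
        frac = (i + 1) / (spec.n_secondary_branches + 1)
        branch_start = soma + np.array([0.0, frac * primary_len])
        sign = 1.0 if i % 2 == 0 else -1.0
        ang = math.radians(rng.uniform(30.0, 60.0)) * sign
        direction = np.array([math.sin(ang), math.cos(ang)])
        segs.append(
            _Segment(
                branch_start,
                direction,
                spec.secondary_path_um * px_per_um,
                "secondary",
                frac * primary_len,
            )
        )
    return segs


def _capsule_pixel_count(
    center_rc: tuple[float, float], length_px: float, width_px: float, angle_deg: float
) -> int:
    """Number of pixels a hard-filled capsule will paint (render math)."""
    probe = np.zeros(
        (int(math.ceil(length_px)) * 2 + 8, int(math.ceil(length_px)) * 2 + 8),
        dtype=np.uint8,
    )
    mid = probe.shape[0] / 2.0
    frac = (center_rc[0] % 1.0, center_rc[1] % 1.0)
    render_capsule(probe, (mid + frac[0], mid + frac[1]), length_px, width_px, angle_deg, 1)
    return int(probe.sum())


def _segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> float:
    """Minimum distance between two 2-D line segments."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.hypot(*r))
    if a <= 1e-12:
        s, t = 0.0, float(np.clip(f / e, 0.0, 1.0))
    else:
        c = float(d1 @ r)
        if e <= 1e-12:
            t, s = 0.0, float(np.clip(-c / a, 0.0, 1.0))
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = float(np.clip((b * f - c * e) / denom, 0.0, 1.0)) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            # reproject after clamping t (Ericson, Real-Time Collision Detection)
            if t < 0.0:
                t = 0.0
                s = float(np.clip(-c / a, 0.0, 1.0))
            elif t > 1.0:
                t = 1.0
                s = float(np.clip((b - c) / a, 0.0, 1.0))
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.hypot(*(closest1 - closest2)))


def _truncnorm_geq1(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 1.0:
            return v
    return 1.0


def gen_dendrite_image(
    spec: ImageSpec,
) -> tuple[np.ndarray, pd.DataFrame, DendriteROI]:
    """Render a two-channel dendrite image with ground-truth morphometry.

    Returns ``(stack, ground_truth, roi)`` where ``stack`` is a (2, H, W)
    uint8 array (page 0: mitochondria channel, page 1: dendrite channel),
    ``ground_truth`` has one row per rendered mitochondrion
    (``true_length_um``, ``true_aspect_ratio``, ``true_area_um2``,
    ``dendrite_class``, ``centroid_row``, ``centroid_col``) and ``roi`` holds
    the primary/secondary dendrite masks.

    Objects are placed at non-overlapping arc positions along the skeleton
    (rejection sampling); failure to place ``n_mito`` objects raises a
    GenerationError reporting how many were placed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    px_per_um = spec.px_per_50um / 50.0
    um_per_px = 1.0 / px_per_um
    h, w = spec.height_px, spec.width_px
    segs = _build_skeleton(spec, rng)

    # sample lognormal lengths (moment-matched to the linear-space mean/sd)
    sigma2 = math.log(1.0 + (spec.length_um_sd / spec.length_um_mean) ** 2)
    mu = math.log(spec.length_um_mean) - sigma2 / 2.0

    placed: list[dict] = []
    placed_geom: list[tuple[np.ndarray, np.ndarray, float]] = []  # (end1, end2, radius)
    seg_weights = np.array([s.length_px for s in segs])
    seg_weights = seg_weights / seg_weights.sum()
    for _ in range(spec.n_mito):
        ok = False
        for _try in range(spec.max_tries_per_object):
            length_um = float(rng.lognormal(mu, math.sqrt(sigma2)))
            ar = _truncnorm_geq1(rng, spec.aspect_ratio_mean, spec.aspect_ratio_sd)
            length_px = length_um * px_per_um
            width_px = length_px / ar
            # truncate the joint (length, AR) distribution at the rendering
            # floor: objects below the segmentation footprint are invisible
            # to the pipeline and must not appear in the ground truth
            footprint = width_px * (length_px - width_px) + math.pi * width_px**2 / 4.0
            if not spec.min_footprint_px <= footprint <= spec.max_footprint_px:
                continue
            si = int(rng.choice(len(segs), p=seg_weights))
            seg = segs[si]
            margin = length_px / 2.0
            # keep secondary objects clear of the branch junction so the ROI
            # disk around the primary path cannot claim their centroid
            min_pos = margin if seg.dendrite_class == "primary" else max(margin, 12.0)
            if seg.length_px - margin <= min_pos:
                continue
            pos = rng.uniform(min_pos, seg.length_px - margin)
            center = seg.start_rc + pos * seg.direction
            if not (
                margin < center[0] < h - margin and margin < center[1] < w - margin
            ):
                continue
            base_angle = math.degrees(math.atan2(seg.direction[0], seg.direction[1]))
            angle = base_angle + rng.uniform(
                -spec.orientation_jitter_deg, spec.orientation_jitter_deg
            )
            th = math.radians(angle)
            axis = np.array([math.sin(th), math.cos(th)])
            half_core = max(length_px - width_px, 0.0) / 2.0
            end1 = center - half_core * axis
            end2 = center + half_core * axis
            radius = width_px / 2.0
            if any(
                _segment_distance(end1, end2, e1, e2) < radius + r2 + spec.clearance_px
                for e1, e2, r2 in placed_geom
            ):
                continue
            # count the pixels this capsule will actually paint (same math as
            # render_capsule) so every ground-truth object clears the area gate
            n_pixels = _capsule_pixel_count(center, length_px, width_px, angle)
            if n_pixels < 5:
                continue
            placed_geom.append((end1, end2, radius))
            width_um = length_um / ar
            true_area_um2 = width_um * (length_um - width_um) + math.pi * width_um**2 / 4.0
            placed.append(
                {
                    "center_rc": (center[0], center[1]),
                    "length_px": length_px,
                    "width_px": width_px,
                    "angle_deg": angle,
                    "true_length_um": length_um,
                    "true_aspect_ratio": ar,
                    "true_area_um2": true_area_um2,
                    "dendrite_class": seg.dendrite_class,
                }
            )
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place mitochondrion {len(placed) + 1} of "
                f"{spec.n_mito} without overlap ({len(placed)} placed); "
                "enlarge the image or reduce n_mito"
            )

    # mitochondria channel: noisy background, then hard-filled capsules
    mito = np.clip(
        rng.normal(spec.background_level, spec.noise_sd, (h, w)), 0, 161
    ).astype(np.uint8)
    lo_i, hi_i = spec.mito_intensity_range
    for obj in placed:
        value = int(rng.integers(lo_i, hi_i + 1))
        render_capsule(
            mito, obj["center_rc"], obj["length_px"], obj["width_px"], obj["angle_deg"], value
        )

    # dendrite channel and ROI masks: rasterize each skeleton class to a 1-px
    # polyline, then take distance-transform neighborhoods
    skel_primary = np.zeros((h, w), dtype=bool)
    skel_secondary = np.zeros((h, w), dtype=bool)
    roi_radius = 6.0 + spec.dendrite_width_px
    primary_cut_px = 50.0 * px_per_um
    for seg in segs:
        n_steps = max(int(seg.length_px * 2), 2)
        s_px = np.linspace(0.0, seg.length_px, n_steps)
        pts = seg.start_rc[None, :] + s_px[:, None] * seg.direction[None, :]
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        if seg.dendrite_class == "primary":
            within = (seg.arc_offset_px + s_px) <= primary_cut_px
            skel_primary[rr[within], cc[within]] = True
            skel_secondary[rr[~within], cc[~within]] = True
        else:
            skel_secondary[rr, cc] = True
    dist_primary = ndimage.distance_transform_edt(~skel_primary)
    dist_secondary = ndimage.distance_transform_edt(~skel_secondary)
    dist_any = np.minimum(dist_primary, dist_secondary)
    dend = np.clip(
        rng.normal(spec.background_level, spec.noise_sd, (h, w)), 0, 161
    ).astype(np.uint8)
    dend[dist_any <= spec.dendrite_width_px / 2.0] = 140
    roi_primary = dist_primary <= roi_radius
    roi_secondary = (dist_secondary <= roi_radius) & ~roi_primary

    gt = pd.DataFrame(
        [
            {
                "true_length_um": o["true_length_um"],
                "true_aspect_ratio": o["true_aspect_ratio"],
                "true_area_um2": o["true_area_um2"],
                "dendrite_class": o["dendrite_class"],
                "centroid_row": o["center_rc"][0],
                "centroid_col": o["center_rc"][1],
            }
            for o in placed
        ],
        columns=[
            "true_length_um",
            "true_aspect_ratio",
            "true_area_um2",
            "dendrite_class",
            "centroid_row",
            "centroid_col",
        ],
    )
    soma = segs[0].start_rc
    stack = np.stack([mito, dend])
    return stack, gt, DendriteROI((soma[0], soma[1]), roi_primary, roi_secondary)
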