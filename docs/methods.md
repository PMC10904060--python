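# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations behind each analysis stage, and states exactly what the
synthetic-data generators emulate — hence what a passing test suite does and
does not demonstrate about real recordings.

## Photometry processing chain

The chain is: per-channel baseline flattening → isosbestic regression →
ΔF/F → temporal binning → hysteresis event detection.

**Baseline flattening.** Slow drift (photobleaching, fluid shifts) is
removed with asymmetric least squares (AsLS): minimize
Σ wᵢ (yᵢ − zᵢ)² + λ Σ (Δ²z)², with wᵢ = p for points above the baseline and
1 − p below, iterated to convergence (≤ 10 iterations). Defaults λ = 1e8,
p = 0.01 at 50 Hz place the baseline's effective cutoff near 0.08 Hz: slow
enough to track a 120-s sinusoidal wander, fast enough to leave sub-second
calcium transients untouched (the asymmetry makes the baseline hug the lower
envelope, so positive transients are not absorbed). The system is solved
with a banded Cholesky factorization (pentadiagonal matrix), O(n) per
iteration. The flattened trace keeps the input mean so the ΔF/F denominator
is unchanged. A cubic-or-lower polynomial fit is available as the
alternative `method="polynomial"`.

**Isosbestic regression.** The 410-nm channel is Ca²⁺-independent, so
artifacts shared between channels (fiber motion, hemodynamic-like
transients) are estimated by ordinary least squares of reference → signal
and subtracted, adding back the fit mean. On synthetic data with a shared
square-pulse artifact at reference gain 1, the fitted slope recovers the
coupling to ~0.3 % and attenuates the artifact by ~99.7 %. A constant
reference leaves the recording unchanged with a warning (undefined slope).

**ΔF/F.** (F − F̄)/F̄ over the whole (flattened, corrected) session. This is
mean-zero by construction and exactly invariant to any common positive gain
on the raw channels — the property that makes thresholds in ΔF/F units
comparable across sessions and rigs.

**Temporal binning before detection.** The detector threshold is the
unscaled 4 × MAD of the baseline-session ΔF/F, which for Gaussian noise is
only ≈ 2.7 σ. Because the threshold is always computed from the same trace
the detector sees, the false-crossing rate is *scale-free*: no amount of
smoothing changes the threshold-to-noise ratio, only the number of
effectively independent samples per second. Detection therefore runs on
non-overlapping bin averages at 4 Hz (0.24-s bins; `detector.decimate_to_hz`
in the config). A pilot grid over bin widths and filter types (boxcar and
Butterworth low-pass at the native rate, bin decimation at 2–5 Hz) selected
this value as the best compromise between noise-driven false events (which
dominate at low event rates) and merging of closely spaced transients
(which dominates at high rates). At the native 50 Hz an unsmoothed detector
fires on noise roughly every 6 s and is unusable.

**Hysteresis detection.** T = k·MAD(baseline ΔF/F) with k = 4; re-arm level
R = 0.9 T. The state machine starts armed, fires on an upward crossing of T
(ties at exactly T count — `>=` — so integer-valued synthetic waveforms
behave deterministically), and re-arms strictly below R. One arming cycle
equals one event; the event's peak is the ΔF/F maximum between the onset and
the re-arm sample. The onset is timestamped at the threshold-crossing
sample, not the peak. The threshold comes from the baseline session only and
is never refreshed within the test session. The MAD is unscaled by default;
`mad_consistency_scaled` multiplies by 1.4826 (Gaussian-consistent) for
users who think in σ units. The implementation is index-jumping
(searchsorted over precomputed crossing lists) and is verified sample-exact
against a naive linear scan.

**Session comparison.** Event frequency is count/duration; the session
effect is the ratio test/baseline (also exposed as percent). A baseline with
zero events returns a flagged, NaN-ratio record instead of raising, because
an empty baseline is a data problem the caller must see, not a crash.

## Mitophagy index

mt-Keima's excitation optimum shifts from ~440 nm at mitochondrial pH ≈ 8
to ~586 nm at lysosomal pH ≈ 4.5, so the pointwise I586/I440 ratio indexes
the acidic (mitophagic) fraction of the reporter population. Channels are
baseline-flattened first. The session scalar is the time-mean of the ratio
(median available via `aggregation="median"`; the mean is the default
because the ratio trace is approximately stationary after flattening), and
induction = 100 · test/baseline percent. The index is exactly invariant to
any common gain and requires strictly positive 440-nm intensities.

## Stimulus-locked responses

F₀ is the mean of the 100-s window immediately before the infusion time.
The default ΔF/F convention divides by F — kept as the primary definition
because the denominator choice materially changes magnitudes — with the
conventional (F − F₀)/F₀ available; both are related by
dff_std = dff_paper/(1 − dff_paper), an identity the tests check to 1e-9.
AUC is the trapezoidal integral of ΔF/F over a window relative to the
injection; the default window runs from the injection to the end of the
recording and is overridable (`--auc-window`). Trials are stacked into
(trial × time) matrices with column mean and SEM = SD/√n; ragged trials are
rejected with instructions to resample rather than silently interpolated.

## Mitochondrial morphometry

**Segmentation.** Binary mask = intensity ∈ [162, 255] (both ends
inclusive; 255 is the 8-bit maximum), connected components at 8-connectivity
(4 available), inclusive area gate [5, 200] px. Only uint8 input is
accepted because the window is defined on 8-bit levels. Survivors are
relabeled 1..n in raster-scan order.

**Shape.** `length_um` is the maximum Feret (caliper) diameter: a straight
N-px segment measures exactly N px, so the 169 px = 50 μm calibration is
honored literally. The moment-ellipse major axis is offered as
`length_method="ellipse"` but reads ≈ 1.155× the extent of a uniform bar and
is therefore not the default. `aspect_ratio` is the major/minor ratio of the
second-central-moment ellipse with a pixel-extent correction: +1/12 px² is
added to each principal-axis variance, treating pixels as unit squares
rather than points. For objects only 2–3 px wide — a 0.75-μm mitochondrion
at the default calibration — the uncorrected minor axis is biased low by up
to ~30 %, and single instances at axis-aligned orientations are quantized
(a 2.5-px-wide capsule renders as either 2 or 3 pixel rows); with the
correction, *population means* recover the true aspect ratio to within
~9 % at every tested orientation. Per-instance aspect ratios of
near-resolution objects remain quantized — an information limit of binary
masks, not of the estimator — so group comparisons should always be made on
cohorts. A 1-px-wide degenerate line gets its minor axis floored at 1 px and
a flag. Area in μm² is the pixel count times the squared pixel size, so
doubling `px_per_50um` halves lengths and quarters areas exactly.

**Dendrite classes.** Objects are classed by centroid membership in
user-supplied (or generator-supplied) primary/secondary ROI masks; the masks
must be disjoint, and objects outside both are `unassigned` and excluded
from per-class summaries. Automated neurite tracing is out of scope.

**Population comparison.** Per-group mean, SEM, n, and ECDFs; two-sample
Kolmogorov–Smirnov D with the asymptotic two-sided p-value (scipy). Groups
under 5 observations flag the p-value as unreliable. D is verified exactly
against a brute-force double-loop supremum.

## Behavioral and respirometry scores

All scores are pure functions of their input tables. CPA is signed seconds
(negative = aversion) and antisymmetric under chamber swap. %MPE is not
floored at 0, so hyperalgesia is representable; it reaches 100 iff the test
latency hits the assay cutoff (60 s hot plate, 30 s tail flick). Tolerance
curves are per-day mean ± SEM with gaps preserved and flagged, never
fitted. SUIT stages are labeled purely from the titration order
(ADP → succinate → CCCP → rotenone → antimycin → CI, CI+II, ETS_max,
ETS_CII, ROX); each stage's flux is the mean over the last 50 % of its
window (configurable `tail_fraction`), approximating steady state after the
titration transient. The stage window is right-open so the sample at the
next titration belongs to the next stage. Fluxes are divided by tissue wet
weight; subtraction of residual (ROX) consumption from the other stages is
opt-in and off by default because the normalization protocol specifies only
weight division.

## Synthetic-data generators

All generators are bit-deterministic given their spec (seed included).

**Photometry traces.** 470-nm channel = baseline level + linear &
sinusoidal drift + shared square-pulse motion artifacts + transients +
white Gaussian noise; 410-nm channel = same drift, the motion scaled by
`gain_410`, independent noise, and no transients. Transients are
peak-normalized difference-of-exponentials kernels
a·(e^(−t/τ_d) − e^(−t/τ_r)) at Poisson onset times; an optional refractory
flag (off by default) enforces a 3 τ_d minimum gap for controlled
merging experiments. Defaults: 50 Hz, baseline 100, noise SD 0.5 raw units
(0.005 ΔF/F), amplitude 0.04 ΔF/F (8× the ΔF/F noise SD), τ_r = 0.05 s,
τ_d = 0.3 s — kinetics representative of fast GCaMP variants; the source
recordings' kinetics and noise are unpublished, so these are free
parameters, chosen once. The square-pulse motion model makes the isosbestic
regression exactly identifiable (the artifact is literally a scaled copy).

**What the trace generator does not emulate:** photon shot noise scaling
with intensity, hemodynamic contamination, slow indicator saturation, or
correlated (pink) noise. Rate-recovery results therefore demonstrate
detector behavior under the stated SNR, not performance on any particular
rig.

**Dual-excitation traces.** I440 = (1 − a)·B₄₄₀,
I586 = a·B₅₈₆ + leak·(1 − a)·B₅₈₆ with acidic fraction a and a 10 % spectral
leak of the neutral population into the 586-nm channel, plus drift and
noise; the expected ratio is strictly increasing in a.

**Stimulus traces.** Flat prestimulus segment, linear ramp (10 s), plateau
(60 s), exponential decay (τ = 60 s). The raw plateau level is
back-computed as F₀·A/(1 − A) so the noise-free (F − F₀)/F plateau equals
the requested amplitude A exactly — which makes closed-form round-trip tests
possible. A consequence worth knowing: ΔF/F under this convention is linear
in the *raw* response amplitude only approximately; the AUC linearity
invariant is checked exactly under the standard convention.

**Dendrite images.** A skeleton of one straight primary dendrite from the
soma (50 μm by default, so the primary class coincides with the ≤ 50 μm
path-distance definition) plus alternating-side secondary branches.
Mitochondria are hard-filled rotated capsules (no anti-aliasing, so
pixel-exact area assertions hold); lengths are lognormal (moment-matched to
the requested linear-space mean/SD), aspect ratios truncated-normal ≥ 1,
orientations follow the local dendrite direction ± 10°. Placement is
rejection sampling with an exact capsule-capsule clearance test (minimum
segment-segment distance); candidates whose *rendered* pixel count would
fall below the 5-px gate, or whose footprint would exceed the 200-px gate,
are resampled — the ground truth contains only objects the segmentation
stage can in principle recover, i.e. the joint (length, AR) distribution is
truncated at the resolution floor exactly as a real gated analysis truncates
it. ROI masks are distance-transform neighborhoods of the skeleton;
secondary placements keep 12 px clear of branch junctions so ROI membership
is unambiguous. Across seeds, ≥ 98 % of ground-truth objects are recovered
with the correct dendrite class.

**What the image generator does not emulate:** the microscope PSF,
deconvolution artifacts, out-of-focus light, intensity falloff within an
object, or mitochondrial networks/branched shapes. Shape-recovery results
quantify discretization behavior of the measurement code, not segmentation
performance on real micrographs.

## Validation studies (mitoscope.validation)

Problem sizes were chosen to give stable medians/fractions at interactive
runtimes: 100 traces for detector-oracle equivalence; 50 seeds × 2 rates ×
600 s for rate recovery; 200 rendered instances per rotation for capsule
recovery; 50 cohort-pair runs (200 measured objects per cohort, accumulated
over as many 420×520 images as needed) for KS power; 100 random sample pairs
for the KS oracle. `scripts/acceptance.py` re-runs all of them from a single
seed in about two minutes.

## Known limitations

* The vendor baseline/motion script used for the original recordings is
  unspecified; AsLS + linear isosbestic regression is this package's own
  choice and is exposed in the config.
* Whether "relative frequency" is a ratio or a percent in the source
  protocol is ambiguous; both are reported.
* The (F − F₀)/F convention is kept as printed even though (F − F₀)/F₀ is
  the field's standard; both are computed, neither intent is guessed.
* Event detection below ~2 SNR or above ~0.3 Hz (where transient tails
  overlap the re-arm level) degrades gracefully but is outside the validated
  envelope.
* Morphometry of objects near the 5-px gate carries irreducible
  quantization; per-object aspect ratios there should not be interpreted
  individually.
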