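"""Dual-excitation mitophagy index and stimulus-locked response metrics.

mt-Keima is a pH-sensitive fluorophore whose excitation shifts from ~440 nm
in neutral mitochondria to ~586 nm once a mitochondrion is delivered to the
acidic lysosome. The 586/440 excitation ratio therefore indexes mitophagy;
sessions are compared as a percentage of the baseline-session ratio.

Stimulus-locked responses (e.g. mitochondrial Ca2+ uptake evoked by
intracranial kaempferol infusion) are expressed as ΔF/F against the mean of a
100-s prestimulus window F0 and summarized by their peak and area under the
curve (AUC). Two ΔF/F conventions are supported: ``"paper"`` divides by F,
``"standard"`` divides by F0; they are related by
``dff_std = dff_paper / (1 - dff_paper)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .photometry import fit_baseline

__all__ = [
    "DualExcitationTrace",
    "MitophagyIndex",
    "StimResponseTrace",
    "ResponseSummary",
    "flatten_dual",
    "mitophagy_index",
    "stim_dff",
    "response_auc",
    "trials_heatmap",
]


@dataclass
class DualExcitationTrace:
    """Fluorescence sampled under alternating 440-nm and 586-nm excitation."""

    time_s: np.ndarray
    ex440: np.ndarray
    ex586: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ex440 = np.asarray(self.ex440, dtype=float)
        self.ex586 = np.asarray(self.ex586, dtype=float)
        if not (self.time_s.size == self.ex440.size == self.ex586.size):
            raise ValidationError("channel lengths differ")
        for name in ("ex440", "ex586"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite samples in {name}")


@dataclass
class MitophagyIndex:
    """586/440 excitation ratio of a test session, normalized to baseline."""

    ratio_t: np.ndarray
    baseline_ratio: float
    test_ratio: float
    relative_induction_pct: float
    aggregation: str = "mean"


@dataclass
class StimResponseTrace:
    """Baseline-corrected fluorescence around a stimulus (infusion) time."""

    time_s: np.ndarray
    F: np.ndarray
    injection_time_s: float
    prestim_window_s: float = 100.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time_s.size != self.F.size:
            raise ValidationError("time and F length mismatch")
        if self.time_s.size and (
            self.injection_time_s - self.prestim_window_s < self.time_s[0] - 1e-9
        ):
            raise ValidationError(
                "prestimulus window extends before the start of the recording"
            )


@dataclass
class ResponseSummary:
    """ΔF/F trace with its F0, peak and AUC over an analysis window."""

    time_s: np.ndarray
    dff_t: np.ndarray
    f0: float
    peak_dff: float
    auc: float
    window_s: tuple[float, float]
    injection_time_s: float
    convention: str = "paper"


def flatten_dual(trace: DualExcitationTrace, **kwargs) -> DualExcitationTrace:
    """Baseline-flatten each excitation channel (AsLS by default)."""
    f440, _ = fit_baseline(trace.ex440, **kwargs)
    f586, _ = fit_baseline(trace.ex586, **kwargs)
    return DualExcitationTrace(trace.time_s, f440, f586)


def mitophagy_index(
    trace: DualExcitationTrace,
    baseline: DualExcitationTrace,
    aggregation: str = "mean",
) -> MitophagyIndex:
    """Pointwise 586/440 ratio and induction relative to the baseline session.

    Both traces are expected to be baseline-flattened (``flatten_dual``). The
    session scalar is the time-mean of the ratio (or median with
    ``aggregation="median"``); induction is ``100 * test / baseline`` percent.
    """
    agg = {"mean": np.mean, "median": np.median}.get(aggregation)
    if agg is None:
        raise ValidationError(f"unknown aggregation: {aggregation!r}")
    for name, tr in (("test", trace), ("baseline", baseline)):
        if np.any(tr.ex440 <= 0):
            raise ValidationError(
                f"mitophagy_index: non-positive ex440 sample in {name} trace"
            )
    ratio_t = trace.ex586 / trace.ex440
    test_scalar = float(agg(ratio_t))
    base_scalar = float(agg(baseline.ex586 / baseline.ex440))
    return MitophagyIndex(
        ratio_t=ratio_t,
        baseline_ratio=base_scalar,
        test_ratio=test_scalar,
        relative_induction_pct=100.0 * test_scalar / base_scalar,
        aggregation=aggregation,
    )


def stim_dff(trace: StimResponseTrace, convention: str = "paper") -> ResponseSummary:
    """Stimulus-locked ΔF/F with F0 from the prestimulus window.

    ``F0`` is the mean of ``F`` over the ``prestim_window_s`` seconds
    preceding the injection. Convention ``"paper"`` computes
    ``(F - F0) / F``; ``"standard"`` computes ``(F - F0) / F0``. The AUC is
    filled over the default window (injection to end of trace); use
    :func:`response_auc` for other windows.
    """
    if convention not in ("paper", "standard"):
        raise ValidationError(f"unknown ΔF/F convention: {convention!r}")
    t = trace.time_s
    t0 = trace.injection_time_s
    pre = (t >= t0 - trace.prestim_window_s) & (t < t0)
    if not pre.any():
        raise ValidationError("stim_dff: no samples in the prestimulus window")
    f0 = float(trace.F[pre].mean())
    if f0 <= 0:
        raise ValidationError("stim_dff: F0 must be positive")
    if convention == "paper":
        if np.any(trace.F <= 0):
            raise ValidationError("stim_dff: F must be positive for the paper convention")
        dff = (trace.F - f0) / trace.F
    else:
        dff = (trace.F - f0) / f0
    post = t >= t0
    summary = ResponseSummary(
        time_s=t,
        dff_t=dff,
        f0=f0,
        peak_dff=float(dff[post].max()) if post.any() else float(dff.max()),
        auc=0.0,
        window_s=(0.0, float(t[-1] - t0)),
        injection_time_s=t0,
        convention=convention,
    )
    summary.auc = response_auc(summary)
    return summary


def response_auc(summary: ResponseSummary, window_s: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of ΔF/F over a window relative to the injection.

    ``window_s`` is ``(start, end)`` in seconds after the injection; the
    default is the summary's stored window (injection to end of trace).
    """
    if window_s is None:
        window_s = summary.window_s
    start, end = window_s
    if start < 0:
        raise ValidationError("response_auc: window start must be >= 0")
    t0 = summary.injection_time_s
    sel = (summary.time_s >= t0 + start) & (summary.time_s <= t0 + end)
    if sel.sum() < 2:
        raise ValidationError("response_auc: empty analysis window")
    return float(np.trapezoid(summary.dff_t[sel], summary.time_s[sel]))


def trials_heatmap(
    summaries: list[ResponseSummary],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack aligned trials into a (trial x time) matrix with mean +/- SEM.

    Returns ``(matrix, mean, sem, time_rel_s)`` where ``time_rel_s`` is time
    relative to the injection. All trials must share the same length and
    sampling; ragged inputs are rejected with a pointer to resample first.
    """
    if not summaries:
        raise ValidationError("trials_heatmap: no trials given")
    n_t = summaries[0].dff_t.size
    if any(s.dff_t.size != n_t for s in summaries):
        raise ValidationError(
            "trials_heatmap: trials have unequal lengths; resample to a common "
            "time base before stacking"
        )
    matrix = np.vstack([s.dff_t for s in summaries])
    mean = matrix.mean(axis=0)
    n = matrix.shape[0]
    sem = matrix.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(n_t)
    time_rel = summaries[0].time_s - summaries[0].injection_time_s
    return matrix, mean, sem, time_rel
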