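"""Behavioral and physiological scalar scores.

Deterministic formulas over human-scored tables: conditioned place aversion
(CPA, time in the withdrawal-paired chamber minus time in the other chamber),
percent maximum possible effect for analgesia assays
(%MPE = 100 * (test - baseline) / (cutoff - baseline), cutoff 60 s for the
hot plate and 30 s for the tail flick), naloxone-precipitated withdrawal
tallies and weight-loss percentage, and substrate-uncoupler-inhibitor
titration (SUIT) respirometry stages with wet-weight flux normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ChamberSession",
    "AnalgesiaTrial",
    "WithdrawalRecord",
    "RespirometryRun",
    "SUIT_ORDER",
    "SUIT_STAGE_LABELS",
    "ASSAY_CUTOFF_S",
    "cpa_score",
    "mpe_percent",
    "tolerance_curve",
    "weight_loss_percent",
    "withdrawal_summary",
    "label_suit_stages",
    "normalize_flux",
]

ASSAY_CUTOFF_S = {"hotplate": 60.0, "tailflick": 30.0}

SUIT_ORDER = ("ADP", "succinate", "CCCP", "rotenone", "antimycin")
SUIT_STAGE_LABELS = {
    "ADP": "CI",
    "succinate": "CI+II",
    "CCCP": "ETS_max",
    "rotenone": "ETS_CII",
    "antimycin": "ROX",
}


@dataclass(frozen=True)
class ChamberSession:
    """Time spent in each chamber of a two-chamber place-conditioning test."""

    time_paired_s: float
    time_other_s: float
    session_length_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.time_paired_s < 0 or self.time_other_s < 0:
            raise ValidationError("chamber times must be >= 0")
        if self.time_paired_s + self.time_other_s > self.session_length_s + 1e-9:
            raise ValidationError("chamber times exceed the session length")


@dataclass(frozen=True)
class AnalgesiaTrial:
    """One latency pair from a hot-plate or tail-flick assay."""

    baseline_latency_s: float
    test_latency_s: float
    assay: str = "hotplate"
    cutoff_s: float | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_CUTOFF_S:
            raise ValidationError(f"unknown assay {self.assay!r}")
        cutoff = self.cutoff_s if self.cutoff_s is not None else ASSAY_CUTOFF_S[self.assay]
        object.__setattr__(self, "cutoff_s", cutoff)
        if not 0 < self.baseline_latency_s < cutoff:
            raise ValidationError("baseline latency must lie in (0, cutoff)")
        if not 0 <= self.test_latency_s <= cutoff:
            raise ValidationError("test latency must lie in [0, cutoff]")


@dataclass(frozen=True)
class WithdrawalRecord:
    """Naloxone-precipitated withdrawal scores for one animal (30-min observation)."""

    weight_before_g: float
    weight_after_g: float
    fecal_boli_count: int = 0
    jumps: int = 0
    wet_dog_shakes: int = 0
    body_tremor: int = 0
    backward_locomotion: int = 0
    piloerection: int = 0

    def __post_init__(self) -> None:
        if self.weight_before_g <= 0 or self.weight_after_g <= 0:
            raise ValidationError("weights must be > 0")
        for name in (
            "fecal_boli_count",
            "jumps",
            "wet_dog_shakes",
            "body_tremor",
            "backward_locomotion",
            "piloerection",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")


@dataclass
class RespirometryRun:
    """O2 flux trace with SUIT titration marks and the tissue wet weight."""

    time_s: np.ndarray
    flux_pmol_s: np.ndarray
    titration_events: list[tuple[float, str]]  # (time_s, reagent)
    wet_weight_mg: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flux_pmol_s = np.asarray(self.flux_pmol_s, dtype=float)
        if self.time_s.size != self.flux_pmol_s.size:
            raise ValidationError("time and flux length mismatch")
        if self.wet_weight_mg <= 0:
            raise ValidationError("wet_weight_mg must be > 0")


def cpa_score(session: ChamberSession) -> float:
    """Signed CPA score in seconds: paired minus other (negative = aversion)."""
    return session.time_paired_s - session.time_other_s


def mpe_percent(trial: AnalgesiaTrial) -> float:
    """Percent maximum possible effect of one analgesia trial.

    100 iff the test latency hits the cutoff; 0 when test equals baseline;
    negative values (hyperalgesia) are allowed and not clamped.
    """
    denom = trial.cutoff_s - trial.baseline_latency_s
    if denom <= 0:
        raise ValidationError("baseline latency must be below the cutoff")
    return 100.0 * (trial.test_latency_s - trial.baseline_latency_s) / denom


def tolerance_curve(trials_by_day: dict[int, list[AnalgesiaTrial]]) -> pd.DataFrame:
    """Per-day group %MPE (mean, SEM, n) across a repeated-dosing schedule.

    Days missing from a contiguous day range are preserved as NaN rows
    flagged in the ``missing`` column. No curve is fitted.
    """
    if len(trials_by_day) < 2:
        raise ValidationError("tolerance_curve: need at least 2 days")
    days = sorted(trials_by_day)
    rows = []
    for day in range(days[0], days[-1] + 1):
        trials = trials_by_day.get(day)
        if not trials:
            rows.append(
                {"day": day, "mean_mpe": np.nan, "sem_mpe": np.nan, "n": 0, "missing": True}
            )
            continue
        mpes = np.array([mpe_percent(tr) for tr in trials])
        sem = float(mpes.std(ddof=1) / np.sqrt(mpes.size)) if mpes.size > 1 else 0.0
        rows.append(
            {
                "day": day,
                "mean_mpe": float(mpes.mean()),
                "sem_mpe": sem,
                "n": int(mpes.size),
                "missing": False,
            }
        )
    return pd.DataFrame(rows, columns=["day", "mean_mpe", "sem_mpe", "n", "missing"])


def weight_loss_percent(rec: WithdrawalRecord) -> float:
    """Weight loss as a percentage of the pre-naloxone weight (may be negative)."""
    return 100.0 * (rec.weight_before_g - rec.weight_after_g) / rec.weight_before_g


def withdrawal_summary(records: list[WithdrawalRecord]) -> pd.DataFrame:
    """One row per animal: symptom counts plus the weight-loss percentage."""
    rows = []
    for i, rec in enumerate(records):
        rows.append(
            {
                "animal": i,
                "weight_loss_pct": weight_loss_percent(rec),
                "fecal_boli_count": rec.fecal_boli_count,
                "jumps": rec.jumps,
                "wet_dog_shakes": rec.wet_dog_shakes,
                "body_tremor": rec.body_tremor,
                "backward_locomotion": rec.backward_locomotion,
                "piloerection": rec.piloerection,
            }
        )
    return pd.DataFrame(rows)


def label_suit_stages(run: RespirometryRun, tail_fraction: float = 0.5) -> pd.DataFrame:
    """Stage means of a SUIT respirometry run.

    Each titration opens a stage window lasting until the next titration (or
    the end of the trace); the stage flux is the mean over the last
    ``tail_fraction`` of the window, approximating steady state. Stages are
    labeled CI (post-ADP), CI+II (post-succinate), ETS_max (post-CCCP),
    ETS_CII (post-rotenone), ROX (post-antimycin). Missing or out-of-order
    reagents are rejected.
    """
    if not 0 < tail_fraction <= 1:
        raise ValidationError("tail_fraction must lie in (0, 1]")
    reagents = [r for _, r in run.titration_events]
    if tuple(reagents) != SUIT_ORDER:
        raise ValidationError(
            "titration events must follow the SUIT protocol order "
            f"{' -> '.join(SUIT_ORDER)} (got {' -> '.join(reagents) or 'none'})"
        )
    times = [t for t, _ in run.titration_events]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("titration times must be strictly increasing")
    rows = []
    bounds = times + [float(run.time_s[-1])]
    for i, reagent in enumerate(reagents):
        t0, t1 = bounds[i], bounds[i + 1]
        tail_start = t1 - tail_fraction * (t1 - t0)
        last = i == len(reagents) - 1
        # right-open window: the sample at the next titration belongs there
        sel = (run.time_s >= tail_start) & (
            (run.time_s <= t1) if last else (run.time_s < t1)
        )
        if not sel.any():
            raise ValidationError(f"no samples in the {reagent} stage window")
        rows.append(
            {
                "stage": SUIT_STAGE_LABELS[reagent],
                "reagent": reagent,
                "t_start_s": t0,
                "t_end_s": t1,
                "mean_flux_pmol_s": float(run.flux_pmol_s[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def normalize_flux(
    stage_table: pd.DataFrame, wet_weight_mg: float, subtract_rox: bool = False
) -> pd.DataFrame:
    """Divide stage fluxes by the tissue wet weight (pmol/s/mg).

    ``subtract_rox`` additionally subtracts the residual (post-antimycin)
    oxygen consumption from the other stages before normalizing; off by
    default.
    """
    if wet_weight_mg <= 0:
        raise ValidationError("wet_weight_mg must be > 0")
    out = stage_table.copy()
    flux = out["mean_flux_pmol_s"].to_numpy(dtype=float)
    if subtract_rox:
        rox_rows = out["stage"] == "ROX"
        if rox_rows.any():
            rox = float(flux[rox_rows.to_numpy()][0])
            flux = np.where(rox_rows.to_numpy(), flux, flux - rox)
    out["flux_per_mg"] = flux / wet_weight_mg
    return out
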