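"""Reading and writing of the package's table and image formats.

Tables are CSV with documented headers; images are 8-bit multi-page TIFF
(page 1 mitochondria, page 2 dendrite). Table round trips preserve values to
full float precision; image round trips are bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .morphometry import DendriteROI
from .photometry import EventSet, RawPhotometry
from .ratiometric import DualExcitationTrace, StimResponseTrace

PHOTOMETRY_COLUMNS = ["time_s", "ch470", "ch410"]
KEIMA_COLUMNS = ["time_s", "ex440", "ex586"]
STIM_COLUMNS = ["time_s", "F"]
EVENT_COLUMNS = ["onset_s", "peak_s", "peak_dff"]


def read_table(path: str | Path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking that every required column is present."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: could not parse CSV ({exc})") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_photometry_csv(raw: RawPhotometry, path: str | Path) -> Path:
    df = pd.DataFrame(
        {"time_s": raw.time_s, "ch470": raw.ch_signal, "ch410": raw.ch_reference}
    )
    return write_table(df, path)


def read_photometry_csv(path: str | Path, sampling_rate_hz: float | None = None) -> RawPhotometry:
    df = read_table(path, PHOTOMETRY_COLUMNS)
    t = df["time_s"].to_numpy()
    if sampling_rate_hz is None:
        if t.size < 2:
            raise ValidationError(f"{path}: cannot infer sampling rate from <2 samples")
        sampling_rate_hz = 1.0 / float(np.diff(t).mean())
    return RawPhotometry(t, df["ch470"].to_numpy(), df["ch410"].to_numpy(), sampling_rate_hz)


def write_keima_csv(trace: DualExcitationTrace, path: str | Path) -> Path:
    df = pd.DataFrame({"time_s": trace.time_s, "ex440": trace.ex440, "ex586": trace.ex586})
    return write_table(df, path)


def read_keima_csv(path: str | Path) -> DualExcitationTrace:
    df = read_table(path, KEIMA_COLUMNS)
    return DualExcitationTrace(
        df["time_s"].to_numpy(), df["ex440"].to_numpy(), df["ex586"].to_numpy()
    )


def write_stim_csv(trace: StimResponseTrace, path: str | Path) -> Path:
    df = pd.DataFrame({"time_s": trace.time_s, "F": trace.F})
    p = write_table(df, path)
    return p


def read_stim_csv(
    path: str | Path, injection_time_s: float, prestim_window_s: float = 100.0
) -> StimResponseTrace:
    df = read_table(path, STIM_COLUMNS)
    return StimResponseTrace(
        df["time_s"].to_numpy(), df["F"].to_numpy(), injection_time_s, prestim_window_s
    )


def write_events_csv(events: EventSet, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "onset_s": events.onset_times_s,
            "peak_s": events.peak_times_s,
            "peak_dff": events.peak_dff,
        }
    )
    return write_table(df, path)


def write_image(stack: np.ndarray, path: str | Path) -> Path:
    """Write an 8-bit image or multi-page stack as TIFF."""
    stack = np.asarray(stack)
    if stack.dtype != np.uint8:
        raise ValidationError("write_image: only 8-bit (uint8) images are written")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack)
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit TIFF; other bit depths are rejected with guidance."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.dtype != np.uint8:
        raise ValidationError(
            f"{path}: expected an 8-bit TIFF (got {stack.dtype}); convert to "
            "uint8 first — the 162-255 intensity window is defined on 8-bit levels"
        )
    return stack


def write_roi(roi: DendriteROI, mask_path: str | Path, soma_path: str | Path) -> None:
    """ROI masks as a 2-page uint8 TIFF (primary, secondary) + soma CSV."""
    stack = np.stack(
        [roi.primary_mask.astype(np.uint8) * 255, roi.secondary_mask.astype(np.uint8) * 255]
    )
    write_image(stack, mask_path)
    write_table(
        pd.DataFrame({"soma_row": [roi.soma_xy[0]], "soma_col": [roi.soma_xy[1]]}),
        soma_path,
    )


def read_roi(mask_path: str | Path, soma_path: str | Path) -> DendriteROI:
    stack = read_image(mask_path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValidationError(f"{mask_path}: ROI TIFF must have exactly 2 pages")
    df = read_table(soma_path, ["soma_row", "soma_col"])
    return DendriteROI(
        (float(df["soma_row"][0]), float(df["soma_col"][0])),
        stack[0] > 0,
        stack[1] > 0,
    )
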