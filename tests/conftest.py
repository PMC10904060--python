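"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (sample-by-sample scans, double-loop
suprema) so they stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitoscope.photometry import DffTrace


def naive_hysteresis_scan(
    x: np.ndarray, threshold: float, rearm: float
) -> tuple[list[int], list[int]]:
    """Sample-by-sample hysteresis scan; returns (onset indices, peak indices).

    Semantics: start armed; fire on x >= threshold (inclusive) and disarm;
    re-arm on x < rearm (strict). Peak is the max between onset and the
    re-arm sample (or the end of the trace).
    """
    onsets: list[int] = []
    peaks: list[int] = []
    armed = True
    current_onset = None
    for i, v in enumerate(x):
        if armed:
            if v >= threshold:
                onsets.append(i)
                current_onset = i
                armed = False
        else:
            if v < rearm:
                seg = x[current_onset : i + 1]
                peaks.append(current_onset + int(np.argmax(seg)))
                armed = True
                current_onset = None
    if current_onset is not None:
        seg = x[current_onset:]
        peaks.append(current_onset + int(np.argmax(seg)))
    return onsets, peaks


def brute_force_ks(x: np.ndarray, y: np.ndarray) -> float:
    """D = sup |ECDF_x - ECDF_y| evaluated at every observed point."""
    support = np.concatenate([x, y])
    d = 0.0
    for v in support:
        fx = np.mean(x <= v)
        fy = np.mean(y <= v)
        d = max(d, abs(fx - fy))
    return float(d)


def make_dff(x: np.ndarray, fs: float = 50.0) -> DffTrace:
    """Wrap a raw array as a DffTrace (unit mean_raw) for detector tests."""
    x = np.asarray(x, dtype=float)
    return DffTrace(np.arange(x.size) / fs, x, mean_raw=1.0, sampling_rate_hz=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
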