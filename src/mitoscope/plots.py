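"""Figure helpers (heatmaps, ECDFs, tolerance curves). Matplotlib Agg only."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def save_trials_heatmap(
    matrix: np.ndarray,
    mean: np.ndarray,
    sem: np.ndarray,
    time_rel_s: np.ndarray,
    path: str | Path,
) -> Path:
    """Trial-by-time ΔF/F heatmap over an average trace with a SEM band."""
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(6, 5), sharex=True, height_ratios=[2, 1]
    )
    extent = [time_rel_s[0], time_rel_s[-1], matrix.shape[0] + 0.5, 0.5]
    im = ax0.imshow(matrix, aspect="auto", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax0, label="ΔF/F")
    ax0.set_ylabel("trial")
    ax1.plot(time_rel_s, mean, color="k")
    ax1.fill_between(time_rel_s, mean - sem, mean + sem, alpha=0.3, color="k")
    ax1.axvline(0.0, color="r", ls="--", lw=0.8)
    ax1.set_xlabel("time from injection (s)")
    ax1.set_ylabel("ΔF/F")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_ecdfs(
    ecdfs: dict[str, tuple[np.ndarray, np.ndarray]], metric: str, path: str | Path
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, (support, cum) in ecdfs.items():
        ax.step(support, cum, where="post", label=name)
    ax.set_xlabel(metric)
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_tolerance_curve(curve: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(curve["day"], curve["mean_mpe"], yerr=curve["sem_mpe"], marker="o")
    ax.set_xlabel("day")
    ax.set_ylabel("%MPE")
    ax.set_ylim(-10, 110)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
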