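"""Run configuration with a single versioned defaults block.

All analysis-defining parameters live here (no hidden defaults at call
sites): detector threshold multiplier and re-arm fraction, segmentation
intensity window and area gate, scale calibration, ΔF/F convention and
prestimulus window, acquisition rate. Unknown keys in a config file are
rejected by name.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

#: Defaults for every stage. The quantification constants mirror the source
#: protocol: 50 Hz acquisition; detector k=4 (xMAD), re-arm at 0.9xT;
#: segmentation window 162-255 with a 5-200 px area gate; 169 px = 50 um;
#: 100-s prestimulus F0 window.
DEFAULTS: dict = {
    "seed": 0,
    "stages": ["simulate", "photometry", "keima", "stim", "morphometry"],
    "outdir": "mitoscope_run",
    "log_level": "INFO",
    "make_figures": False,
    "acquisition": {"sampling_rate_hz": 50.0},
    "baseline": {"method": "asls", "lam": 1.0e8, "p": 0.01},
    "detector": {
        "k": 4.0,
        "rearm_fraction": 0.9,
        "mad_scaled": False,
        "decimate_to_hz": 4.0,
    },
    "dff": {"convention": "paper", "prestim_window_s": 100.0, "auc_window_s": None},
    "segmentation": {
        "intensity_lo": 162,
        "intensity_hi": 255,
        "min_area_px": 5,
        "max_area_px": 200,
        "connectivity": 8,
    },
    "calibration": {"px_per_50um": 169.0},
    "simulate": {
        "trace": {"duration_s": 300.0, "event_rate_hz": 0.1},
        "keima": {"baseline_acidic_fraction": 0.1, "test_acidic_fraction": 0.3},
        "stim": {"response_amplitude": 0.2, "injection_time_s": 120.0},
        "image": {"n_mito": 30, "length_um_mean": 2.0},
    },
    "inputs": {},
}


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, *keys, default=None):
        node = self.values
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValidationError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config merged over the defaults; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
    merged = _merge(DEFAULTS, data)
    if overrides:
        merged = _merge(merged, overrides)
    return RunConfig(merged)


def dump_config(config: RunConfig, path: str | Path) -> Path:
    """Write the resolved configuration alongside the run outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.values, fh, sort_keys=True)
    return path
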