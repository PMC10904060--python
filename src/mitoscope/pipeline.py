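"""End-to-end orchestration: simulate, analyze, and report.

``run_pipeline`` executes the requested stages in dependency order, writes
every table and (optionally) figure under the configured output directory,
and records a manifest with input checksums, the resolved parameter
snapshot, per-stage outputs, and the headline numbers each stage produced.
The report is generated from the manifest alone, so regenerating it from the
manifest file reproduces it byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, dump_config, load_config
from .errors import ValidationError
from .morphometry import ScaleCalibration, SegmentationParams, ks_two_sample, measure_image, summarize
from .photometry import (
    DetectorParams,
    detect_events,
    preprocess_session,
    relative_frequency,
)
from .ratiometric import flatten_dual, mitophagy_index, response_auc, stim_dff, trials_heatmap
from .synthetic import (
    ImageSpec,
    KeimaSpec,
    StimSpec,
    TraceSpec,
    gen_dendrite_image,
    gen_keima_trace,
    gen_photometry_trace,
    gen_stim_trace,
)
from . import io as mio

log = logging.getLogger("mitoscope")

STAGE_ORDER = ["simulate", "photometry", "keima", "stim", "morphometry", "scores"]


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to regenerate its report."""

    version: str
    seed: int
    params: dict
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)  # stage -> [paths]
    summaries: dict = field(default_factory=dict)  # stage -> headline numbers
    completed: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "params": self.params,
                "inputs": self.inputs,
                "outputs": self.outputs,
                "summaries": self.summaries,
                "completed": self.completed,
                "failed_stage": self.failed_stage,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(
            version=d["version"],
            seed=d["seed"],
            params=d["params"],
            inputs=d["inputs"],
            outputs=d["outputs"],
            summaries=d["summaries"],
            completed=d["completed"],
            failed_stage=d.get("failed_stage"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict:
    seed = int(cfg["seed"])
    fs = cfg.get("acquisition", "sampling_rate_hz", default=50.0)
    sim = cfg["simulate"]
    outputs = []

    base_spec = TraceSpec(
        duration_s=sim["trace"]["duration_s"],
        sampling_rate_hz=fs,
        event_rate_hz=sim["trace"]["event_rate_hz"],
        seed=seed,
    )
    test_spec = TraceSpec(
        duration_s=sim["trace"]["duration_s"],
        sampling_rate_hz=fs,
        event_rate_hz=sim["trace"]["event_rate_hz"],
        seed=seed + 1,
    )
    paths = {}
    for name, spec in [("baseline", base_spec), ("test", test_spec)]:
        raw, truth = gen_photometry_trace(spec)
        p = mio.write_photometry_csv(raw, outdir / f"photometry_{name}.csv")
        tp = mio.write_table(
            pd.DataFrame({"onset_s": truth.onset_times_s}),
            outdir / f"photometry_{name}_truth.csv",
        )
        outputs += [p, tp]
        paths[name] = p

    for name, frac_key, s_off in [("baseline", "baseline_acidic_fraction", 2), ("test", "test_acidic_fraction", 3)]:
        ktrace = gen_keima_trace(
            KeimaSpec(acidic_fraction=sim["keima"][frac_key], seed=seed + s_off)
        )
        outputs.append(mio.write_keima_csv(ktrace, outdir / f"keima_{name}.csv"))

    stim = gen_stim_trace(
        StimSpec(
            response_amplitude=sim["stim"]["response_amplitude"],
            injection_time_s=sim["stim"]["injection_time_s"],
            sampling_rate_hz=fs,
            seed=seed + 4,
        )
    )
    outputs.append(mio.write_stim_csv(stim, outdir / "stim_trace.csv"))

    stack, gt, roi = gen_dendrite_image(
        ImageSpec(
            n_mito=sim["image"]["n_mito"],
            length_um_mean=sim["image"]["length_um_mean"],
            px_per_50um=cfg.get("calibration", "px_per_50um", default=169.0),
            seed=seed + 5,
        )
    )
    outputs.append(mio.write_image(stack, outdir / "dendrite_image.tif"))
    outputs.append(mio.write_table(gt, outdir / "dendrite_ground_truth.csv"))
    mio.write_roi(roi, outdir / "dendrite_roi.tif", outdir / "dendrite_soma.csv")
    outputs += [outdir / "dendrite_roi.tif", outdir / "dendrite_soma.csv"]

    manifest.outputs["simulate"] = [str(p) for p in outputs]
    return {"n_outputs": len(outputs), "seed": seed}


def _photometry_paths(cfg: RunConfig, outdir: Path) -> tuple[Path, Path]:
    inputs = cfg.get("inputs", default={}) or {}
    base = Path(inputs.get("photometry_baseline", outdir / "photometry_baseline.csv"))
    test = Path(inputs.get("photometry_test", outdir / "photometry_test.csv"))
    return base, test


def _stage_photometry(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict:
    fs = cfg.get("acquisition", "sampling_rate_hz", default=50.0)
    det = cfg["detector"]
    params = DetectorParams(
        mad_multiplier=det["k"],
        rearm_fraction=det["rearm_fraction"],
        mad_consistency_scaled=det["mad_scaled"],
    )
    base_path, test_path = _photometry_paths(cfg, outdir)
    for p in (base_path, test_path):
        if not p.exists():
            raise ValidationError(f"photometry input missing: {p}")
        manifest.inputs[str(p)] = _sha256(p)
    kw = dict(
        baseline_method=cfg.get("baseline", "method", default="asls"),
        lam=cfg.get("baseline", "lam", default=1e8),
        p=cfg.get("baseline", "p", default=0.01),
        decimate_to_hz=det.get("decimate_to_hz", 4.0),
    )
    base_raw = mio.read_photometry_csv(base_path, fs)
    test_raw = mio.read_photometry_csv(test_path, fs)
    base_dff = preprocess_session(base_raw, **kw)
    test_dff = preprocess_session(test_raw, **kw)
    base_events = detect_events(base_dff, base_dff, params)
    test_events = detect_events(test_dff, base_dff, params)
    comparison = relative_frequency(
        base_events, base_raw.duration_s, test_events, test_raw.duration_s
    )
    outputs = [
        mio.write_events_csv(base_events, outdir / "events_baseline.csv"),
        mio.write_events_csv(test_events, outdir / "events_test.csv"),
    ]
    manifest.outputs["photometry"] = [str(p) for p in outputs]
    return {
        "threshold_dff": base_events.threshold_used,
        "detector_k": params.mad_multiplier,
        "detector_rearm_fraction": params.rearm_fraction,
        "baseline_frequency_hz": comparison.baseline_frequency_hz,
        "test_frequency_hz": comparison.test_frequency_hz,
        "relative_frequency": comparison.relative_frequency
        if comparison.defined
        else None,
    }


def _stage_keima(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict:
    inputs = cfg.get("inputs", default={}) or {}
    base_path = Path(inputs.get("keima_baseline", outdir / "keima_baseline.csv"))
    test_path = Path(inputs.get("keima_test", outdir / "keima_test.csv"))
    for p in (base_path, test_path):
        if not p.exists():
            raise ValidationError(f"keima input missing: {p}")
        manifest.inputs[str(p)] = _sha256(p)
    base = flatten_dual(mio.read_keima_csv(base_path))
    test = flatten_dual(mio.read_keima_csv(test_path))
    index = mitophagy_index(test, base)
    out = mio.write_table(
        pd.DataFrame(
            {
                "baseline_ratio": [index.baseline_ratio],
                "test_ratio": [index.test_ratio],
                "relative_induction_pct": [index.relative_induction_pct],
            }
        ),
        outdir / "mitophagy_index.csv",
    )
    manifest.outputs["keima"] = [str(out)]
    return {
        "baseline_ratio": index.baseline_ratio,
        "test_ratio": index.test_ratio,
        "relative_induction_pct": index.relative_induction_pct,
    }


def _stage_stim(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict:
    inputs = cfg.get("inputs", default={}) or {}
    path = Path(inputs.get("stim_trace", outdir / "stim_trace.csv"))
    if not path.exists():
        raise ValidationError(f"stim input missing: {path}")
    manifest.inputs[str(path)] = _sha256(path)
    trace = mio.read_stim_csv(
        path,
        injection_time_s=cfg.get("simulate", "stim", "injection_time_s", default=120.0),
        prestim_window_s=cfg.get("dff", "prestim_window_s", default=100.0),
    )
    summary = stim_dff(trace, cfg.get("dff", "convention", default="paper"))
    auc_window = cfg.get("dff", "auc_window_s")
    auc = response_auc(summary, tuple(auc_window) if auc_window else None)
    out = mio.write_table(
        pd.DataFrame(
            {
                "f0": [summary.f0],
                "peak_dff": [summary.peak_dff],
                "auc": [auc],
                "convention": [summary.convention],
            }
        ),
        outdir / "stim_response.csv",
    )
    outputs = [out]
    if cfg.get("make_figures", default=False):
        from .plots import save_trials_heatmap

        matrix, mean, sem, trel = trials_heatmap([summary])
        outputs.append(
            save_trials_heatmap(matrix, mean, sem, trel, outdir / "stim_heatmap.png")
        )
    manifest.outputs["stim"] = [str(p) for p in outputs]
    return {"f0": summary.f0, "peak_dff": summary.peak_dff, "auc": auc}


def _stage_morphometry(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict:
    inputs = cfg.get("inputs", default={}) or {}
    img_path = Path(inputs.get("image", outdir / "dendrite_image.tif"))
    roi_path = Path(inputs.get("roi", outdir / "dendrite_roi.tif"))
    soma_path = Path(inputs.get("soma", outdir / "dendrite_soma.csv"))
    if not img_path.exists():
        raise ValidationError(f"morphometry input missing: {img_path}")
    manifest.inputs[str(img_path)] = _sha256(img_path)
    stack = mio.read_image(img_path)
    mito_channel = stack[0] if stack.ndim == 3 else stack
    seg = cfg["segmentation"]
    params = SegmentationParams(
        intensity_lo=seg["intensity_lo"],
        intensity_hi=seg["intensity_hi"],
        min_area_px=seg["min_area_px"],
        max_area_px=seg["max_area_px"],
        connectivity=seg["connectivity"],
    )
    cal = ScaleCalibration(cfg.get("calibration", "px_per_50um", default=169.0))
    roi = mio.read_roi(roi_path, soma_path) if roi_path.exists() else None
    table = measure_image(mito_channel, params, cal, roi)
    outputs = [mio.write_table(table, outdir / "morphometry.csv")]
    summary: dict = {"n_objects": int(len(table))}
    if roi is not None and len(table):
        stats_df, ecdfs = summarize(table, "length_um")
        outputs.append(mio.write_table(stats_df, outdir / "morphometry_by_class.csv"))
        classed = table[table["class"] != "unassigned"]
        groups = classed.groupby("class")["length_um"]
        if len(groups) == 2:
            (n1, x), (n2, y) = list(groups)
            ks = ks_two_sample(x.to_numpy(), y.to_numpy())
            summary["ks_length_D"] = ks.statistic
            summary["ks_length_p"] = ks.pvalue
        if cfg.get("make_figures", default=False):
            from .plots import save_ecdfs

            outputs.append(save_ecdfs(ecdfs, "length_um", outdir / "length_ecdf.png"))
        for _, row in stats_df.iterrows():
            summary[f"mean_length_um_{row.iloc[0]}"] = row["mean"]
    manifest.outputs["morphometry"] = [str(p) for p in outputs]
    return summary


_STAGES = {
    "simulate": _stage_simulate,
    "photometry": _stage_photometry,
    "keima": _stage_keima,
    "stim": _stage_stim,
    "morphometry": _stage_morphometry,
}


def run_pipeline(config: RunConfig | str | Path | None = None) -> RunManifest:
    """Execute the configured stages and write outputs + manifest + report."""
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config["log_level"]), logging.INFO))
    manifest = RunManifest(
        version=__version__, seed=int(config["seed"]), params=config.values
    )
    stages = [s for s in STAGE_ORDER if s in config["stages"]]
    unknown = set(config["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
    dump_config(config, outdir / "resolved_config.yaml")
    for stage in stages:
        if stage == "scores":
            continue  # scores are table-level helpers; no default pipeline stage
        log.info("running stage %s", stage)
        try:
            manifest.summaries[stage] = _STAGES[stage](config, outdir, manifest)
            manifest.completed.append(stage)
        except Exception:
            manifest.failed_stage = stage
            (outdir / "manifest.json").write_text(manifest.to_json())
            raise
    (outdir / "manifest.json").write_text(manifest.to_json())
    (outdir / "report.txt").write_text(report(manifest))
    return manifest


def report(manifest: RunManifest) -> str:
    """Human-readable per-stage headline summary, built from the manifest only."""
    lines = [
        f"mitoscope run report (package version {manifest.version}, seed {manifest.seed})",
        "",
    ]
    if not manifest.completed:
        lines.append("no stages completed")
    for stage in manifest.completed:
        lines.append(f"[{stage}]")
        for key, value in sorted(manifest.summaries.get(stage, {}).items()):
            if isinstance(value, float):
                lines.append(f"  {key}: {value:.6g}")
            else:
                lines.append(f"  {key}: {value}")
        for out in manifest.outputs.get(stage, []):
            lines.append(f"  wrote: {out}")
        lines.append("")
    return "\n".join(lines) + "\n"
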