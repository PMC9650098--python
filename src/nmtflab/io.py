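"""File formats, run configuration and the end-to-end pipeline.

Force recordings travel as CSV (time_s, force_N, nerve_stim, muscle_stim)
with a JSON sidecar holding sampling rate, prep metadata, protocol and,
for synthetic data, the generator ground truth.  NMJ stacks travel as
multi-page TIFF (pages channel-major: all post-synaptic slices, then all
pre-synaptic slices) with a JSON sidecar holding calibration and ground
truth.  A run is reproducible from (config, seed) alone; the manifest
records the config hash, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .force_sim import (
    GROUP_CALIBRATIONS,
    FailureModel,
    ForceRecording,
    PrepMetadata,
    StimulationProtocol,
    simulate_cohort,
)
from .nmj_sim import NMJStack, generate_nmj_cohort
from .morphometry import analyze_nmj_cohort
from .stats import make_report, power_n_per_group
from .trace import analyze_trace_cohort

TRACE_COLUMNS = ["time_s", "force_N", "nerve_stim", "muscle_stim"]


def write_trace(recording: ForceRecording, prefix: Path | str) -> tuple[Path, Path]:
    """Write a recording as ``<prefix>.csv`` + ``<prefix>.json``.

    Floats are serialized with 10 significant digits so a round trip is
    identity to well below 1e-9 relative error.
    """
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    df = pd.DataFrame({
        "time_s": recording.time_s,
        "force_N": recording.force_n,
        "nerve_stim": recording.nerve_stim_marker.astype(int),
        "muscle_stim": recording.muscle_stim_marker.astype(int),
    })
    df.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        **recording.metadata.to_dict(),
        "protocol": recording.protocol.to_dict(),
    }
    if recording.ground_truth is not None:
        sidecar["ground_truth"] = recording.ground_truth.to_dict()
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_trace(prefix: Path | str) -> ForceRecording:
    """Read a recording written by :func:`write_trace` (or any CSV+sidecar
    pair following the same schema)."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    df = pd.read_csv(csv_path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV is missing column(s): {', '.join(missing)}")
    sidecar = json.loads(json_path.read_text())
    if sidecar.get("Lo_cm", 1.0) <= 0 or sidecar.get("strip_weight_g", 1.0) <= 0:
        raise ValueError("sidecar Lo_cm and strip_weight_g must be positive")
    meta = PrepMetadata(
        strip_weight_g=sidecar["strip_weight_g"],
        optimal_length_cm=sidecar["Lo_cm"],
        group=sidecar["group"],
        animal_id=sidecar["animal_id"],
        sex=sidecar.get("sex", ""),
    )
    protocol = StimulationProtocol(**sidecar["protocol"])
    return ForceRecording(
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        time_s=df["time_s"].to_numpy(),
        force_n=df["force_N"].to_numpy(),
        nerve_stim_marker=df["nerve_stim"].to_numpy().astype(np.uint8),
        muscle_stim_marker=df["muscle_stim"].to_numpy().astype(np.uint8),
        metadata=meta,
        protocol=protocol,
    )


def write_stack(stack: NMJStack, prefix: Path | str,
                ground_truth: dict | None = None) -> tuple[Path, Path]:
    """Write a stack as channel-major multi-page TIFF + JSON sidecar."""
    prefix = Path(prefix)
    tif_path = prefix.with_suffix(".tif")
    json_path = prefix.with_suffix(".json")
    pages = np.concatenate([stack.post, stack.pre], axis=0)
    tifffile.imwrite(tif_path, pages)
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "n_slices": stack.n_slices,
        "channels": ["BTX", "SYN"],
        "provenance": {k: v for k, v in stack.provenance.items()},
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    json_path.write_text(json.dumps(sidecar, indent=1, default=float))
    return tif_path, json_path


def read_stack(prefix: Path | str) -> NMJStack:
    """Read a stack written by :func:`write_stack`; lossless for integer data."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    if "pixel_size_um" not in sidecar:
        raise ValueError("sidecar is missing pixel_size_um")
    channels = sidecar.get("channels", ["BTX", "SYN"])
    if len(channels) != 2:
        raise ValueError(f"unsupported channel count: {len(channels)}")
    pages = tifffile.imread(prefix.with_suffix(".tif"))
    n_slices = int(sidecar["n_slices"])
    if pages.shape[0] != 2 * n_slices:
        raise ValueError(
            f"page count {pages.shape[0]} != n_slices x 2 = {2 * n_slices}")
    return NMJStack(
        post=pages[:n_slices],
        pre=pages[n_slices:],
        pixel_size_um=float(sidecar["pixel_size_um"]),
        z_step_um=float(sidecar["z_step_um"]),
        provenance=sidecar.get("provenance", {}),
    )


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_per_group": 8,
    "trace_noise_sd": 0.005,
    "jitter_cv": 0.05,
    "f0_jitter_sd": 0.03,
    "sampling_rate_hz": 1000.0,
    "protocol": {},
    "calibrations": None,  # None -> per-group defaults
    "nmj": {
        "n_per_class_per_animal": 5,
        "n_animals": 4,
        "excluded_fraction": 0.0,
    },
    "threshold": "otsu",
    "posthoc": "tukey",
    "power_reference": {"mean": 59.0, "sd": 8.5, "detectable_fraction": 0.20},
}


def load_config(path: Path | str | None) -> dict:
    """Load a YAML/JSON run config, filling unspecified keys with defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _calibrations_from_config(cfg: dict) -> dict[str, FailureModel] | None:
    raw = cfg.get("calibrations")
    if raw is None:
        return None
    return {g: FailureModel(**params) for g, params in raw.items()}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_end_to_end(cfg: dict, out_dir: Path | str, seed: int | None = None) -> dict:
    """simulate -> analyze -> report; returns the manifest.

    Deterministic: rerunning with the same config and seed reproduces every
    output byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = dict(cfg, seed=int(seed))
    base_seed = int(cfg["seed"])
    protocol = StimulationProtocol(**cfg.get("protocol") or {})

    cohort = simulate_cohort(
        n_per_group=int(cfg["n_per_group"]),
        calibrations=_calibrations_from_config(cfg),
        base_seed=base_seed,
        protocol=protocol,
        sampling_rate_hz=float(cfg["sampling_rate_hz"]),
        jitter_cv=float(cfg["jitter_cv"]),
        f0_jitter_sd=float(cfg["f0_jitter_sd"]),
        noise_sd=float(cfg["trace_noise_sd"]),
    )
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    for rec, _ in cohort:
        write_trace(rec, traces_dir / rec.metadata.animal_id.replace("+", "_"))
    wide, long = analyze_trace_cohort([rec for rec, _ in cohort])
    wide.to_csv(out / "trace_per_animal.csv", index=False)
    long.to_csv(out / "trace_per_epoch.csv", index=False)

    nmj_cfg = cfg["nmj"]
    nmj = generate_nmj_cohort(
        n_per_class_per_animal=int(nmj_cfg["n_per_class_per_animal"]),
        n_animals=int(nmj_cfg["n_animals"]),
        seed=base_seed + 1,
        excluded_fraction=float(nmj_cfg.get("excluded_fraction", 0.0)),
    )
    nmj_dir = out / "nmj"
    nmj_dir.mkdir(exist_ok=True)
    for i, (stack, gt, meta) in enumerate(nmj):
        write_stack(stack, nmj_dir / f"nmj_{i:03d}", ground_truth=gt.to_dict())
    per_nmj, per_class, per_animal = analyze_nmj_cohort(
        [(stack, {**meta}) for stack, _, meta in nmj],
        threshold=cfg["threshold"],
    )
    per_nmj.to_csv(out / "nmj_per_nmj.csv", index=False)
    per_class.to_csv(out / "nmj_per_animal_class.csv", index=False)
    per_animal.to_csv(out / "nmj_per_animal.csv", index=False)

    report, posthoc = make_report(wide, long, per_class, posthoc=cfg["posthoc"])
    report.to_csv(out / "anova_report.csv", index=False)
    posthoc.to_csv(out / "posthoc_report.csv", index=False)

    pw = cfg["power_reference"]
    n_required = power_n_per_group(pw["mean"], pw["sd"], pw["detectable_fraction"])
    manifest = {
        "version": __version__,
        "seed": base_seed,
        "config_sha256": config_hash(cfg),
        "n_per_group": int(cfg["n_per_group"]),
        "n_per_group_required_for_power": n_required,
        "underpowered": int(cfg["n_per_group"]) < n_required,
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
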