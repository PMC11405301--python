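"""Stage orchestration: file-based pipeline runs with manifests.

Each stage reads its inputs from disk, runs the corresponding library
functions, and writes deterministic artifacts plus a ``manifest.json``
(inputs, parameters, seed, package version) under the output directory.
The CLI is a thin wrapper over these functions; they are equally usable
from Python.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import SegmentationParams, segment_contacts
from .electrodes import (
    BuildParams,
    assign_labels,
    brain_center,
    build_electrodes,
    electrodes_table,
    number_contacts,
)
from .phantom import PhantomSpec, GroundTruth, default_trajectories, make_ct_phantom, make_recording
from .scene import build_scene, build_timeline, export_gltf
from .signals import (
    FilterSpec,
    apply_filters,
    crop_around_event,
    match_channels,
    minmax_normalize,
    read_recording,
    windowed_power,
)
from .validate import match_contacts
from .volumes import canonicalize_orientation, read_volume, write_volume


class PrerequisiteError(FileNotFoundError):
    """An upstream artifact is missing; names the stage that produces it."""


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the pipeline's standard operating
    point (99.5th/40th percentile thresholds, 3 erosions, 15 mm / 20°
    electrode building, 60 Hz notch, 80–250 Hz band, N = 24, ±2 s clip,
    6 cm maximum contact size)."""

    output_dir: str = "seegviz_out"
    ct: str | None = None
    brain_mask: str | None = None
    tissue_masks: dict[str, str] = field(default_factory=dict)
    edf: str | None = None
    name_map: dict[str, Any] = field(default_factory=dict)
    reference_contacts: str | None = None
    event_label: str = "seizure onset"
    pre_s: float = 2.0
    post_s: float = 2.0
    notch_hz: float = 60.0
    band_lo_hz: float = 80.0
    band_hi_hz: float = 250.0
    window_n: int = 24
    max_size_mm: float = 60.0
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    build: BuildParams = field(default_factory=BuildParams)
    phantom_electrodes: int = 2
    phantom_contacts: int = 6
    phantom_streaks: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        build = BuildParams(**raw.pop("build", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(segmentation=seg, build=build, **raw)


def _write_manifest(outdir: Path, stage: str, cfg: PipelineConfig, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "seegviz_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": _jsonable(asdict(cfg)),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.output_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise PrerequisiteError(
            f"missing artifact {path}; run the {producer!r} subcommand first"
        )
    return Path(path)


def run_phantom(cfg: PipelineConfig) -> Path:
    """Generate the synthetic study: CT, masks, ground truth, EDF."""
    out = _stage_dir(cfg, "phantom")
    trajectories = default_trajectories(
        cfg.phantom_electrodes,
        [cfg.phantom_contacts] * cfg.phantom_electrodes,
        PhantomSpec.brain_semiaxes_mm,
        PhantomSpec.contact_spacing_mm,
    )
    spec = PhantomSpec(
        electrodes=trajectories, streak_count=cfg.phantom_streaks, seed=cfg.seed
    )
    ct, brain, truth = make_ct_phantom(spec)
    write_volume(ct, out / "ct.nii.gz")
    write_volume(brain, out / "brain_mask.nii.gz", dtype=np.uint8)
    for name, mask in truth.tissue_masks.items():
        write_volume(mask, out / f"{name}.nii.gz", dtype=np.uint8)
    truth.contacts.to_csv(out / "truth.tsv", sep="\t", index=False)
    edf_path, truth = make_recording(truth, out / "recording.edf", seed=cfg.seed)
    truth.burst_onsets.to_csv(out / "burst_onsets.tsv", sep="\t", index=False)
    name_map = {
        t.label: [float(v) for v in t.contact_centers(spec.contact_spacing_mm)[-1]]
        for t in trajectories
    }
    (out / "name_map.yaml").write_text(yaml.safe_dump(name_map))
    _write_manifest(out, "phantom", cfg, {"n_contacts": len(truth.contacts)})
    return out


def _phantom_defaults(cfg: PipelineConfig, key: str, stage_file: str) -> str:
    val = getattr(cfg, key)
    if val:
        return val
    return str(Path(cfg.output_dir) / "phantom" / stage_file)


def run_segment(cfg: PipelineConfig) -> Path:
    out = _stage_dir(cfg, "segment")
    ct_path = _require(Path(_phantom_defaults(cfg, "ct", "ct.nii.gz")), "phantom")
    mask_path = _require(
        Path(_phantom_defaults(cfg, "brain_mask", "brain_mask.nii.gz")), "phantom"
    )
    ct = canonicalize_orientation(read_volume(ct_path))
    mask = canonicalize_orientation(read_volume(mask_path))
    contact_set = segment_contacts(ct, mask, cfg.segmentation)
    contact_set.to_table().to_csv(out / "contacts.tsv", sep="\t", index=False)
    write_volume(contact_set.to_label_volume(), out / "contact_labels.nii.gz",
                 dtype=np.int16)
    _write_manifest(
        out, "segment", cfg,
        {"inputs": [str(ct_path), str(mask_path)],
         "n_contacts": len(contact_set.contacts)},
    )
    return out


def run_electrodes(cfg: PipelineConfig) -> Path:
    out = _stage_dir(cfg, "electrodes")
    contacts_path = _require(
        Path(cfg.output_dir) / "segment" / "contacts.tsv", "segment"
    )
    mask_path = _require(
        Path(_phantom_defaults(cfg, "brain_mask", "brain_mask.nii.gz")), "phantom"
    )
    table = pd.read_csv(contacts_path, sep="\t")
    pts = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
    mask = canonicalize_orientation(read_volume(mask_path))
    center = brain_center(mask)
    name_map = cfg.name_map
    if isinstance(name_map, str):
        name_map = yaml.safe_load(Path(name_map).read_text())
    else:
        default_map = Path(cfg.output_dir) / "phantom" / "name_map.yaml"
        if not name_map and default_map.exists():
            name_map = yaml.safe_load(default_map.read_text())
    electrodes = build_electrodes(pts, center, cfg.build)
    electrodes = [number_contacts(e, center) for e in electrodes]
    electrodes = assign_labels(electrodes, name_map, cfg.build)
    electrodes_table(electrodes).to_csv(out / "electrodes.tsv", sep="\t", index=False)
    _write_manifest(out, "electrodes", cfg, {"n_electrodes": len(electrodes)})
    return out


def run_signal(cfg: PipelineConfig) -> Path:
    out = _stage_dir(cfg, "signal")
    edf_path = _require(
        Path(_phantom_defaults(cfg, "edf", "recording.edf")), "phantom"
    )
    rec = read_recording(edf_path)
    clip, event_in_clip = crop_around_event(rec, cfg.event_label, cfg.pre_s, cfg.post_s)
    spec = FilterSpec(cfg.notch_hz, cfg.band_lo_hz, cfg.band_hi_hz)
    filtered = apply_filters(clip, spec)
    trace = minmax_normalize(windowed_power(filtered, cfg.window_n))
    trace.to_table().to_csv(out / "power.tsv", sep="\t")
    meta = {
        "event_label": cfg.event_label,
        "event_s_in_clip": event_in_clip,
        "clip_s": clip.duration_s,
        "fs": clip.fs,
        "window_n": cfg.window_n,
        "n_windows": trace.n_windows,
    }
    (out / "power_meta.json").write_text(json.dumps(meta, indent=2))
    _write_manifest(out, "signal", cfg, {"inputs": [str(edf_path)], **meta})
    return out


def run_animate(cfg: PipelineConfig) -> Path:
    out = _stage_dir(cfg, "animate")
    elec_path = _require(
        Path(cfg.output_dir) / "electrodes" / "electrodes.tsv", "electrodes"
    )
    power_path = _require(Path(cfg.output_dir) / "signal" / "power.tsv", "signal")
    meta_path = _require(Path(cfg.output_dir) / "signal" / "power_meta.json", "signal")
    table = pd.read_csv(elec_path, sep="\t")
    meta = json.loads(meta_path.read_text())
    power = pd.read_csv(power_path, sep="\t", index_col="contact")

    tissue_masks = {}
    for role in ("gray", "white", "csf"):
        p = cfg.tissue_masks.get(role) or str(
            Path(cfg.output_dir) / "phantom" / f"{role}.nii.gz"
        )
        if Path(p).exists():
            tissue_masks[role] = canonicalize_orientation(read_volume(p))

    from .signals import PowerTrace

    trace = PowerTrace(
        power.to_numpy(), list(power.index), meta["window_n"], meta["fs"],
        normalized=True,
    )
    names = list(table["contact_name"])
    trace, excluded = match_channels(trace, names)
    centers = table.set_index("contact_name").loc[
        trace.channels, ["x_mm", "y_mm", "z_mm"]
    ].to_numpy()
    timeline = build_timeline(meta["clip_s"], meta["event_s_in_clip"])
    model = build_scene(tissue_masks, trace.channels, centers, trace, timeline)
    gltf_path = export_gltf(model, out / "scene.gltf")
    _write_manifest(
        out, "animate", cfg,
        {"gltf": str(gltf_path), "excluded_channels": excluded,
         "animation_s": trace.n_windows},
    )
    return out


def run_validate(cfg: PipelineConfig) -> Path:
    out = _stage_dir(cfg, "validate")
    auto_path = _require(Path(cfg.output_dir) / "segment" / "contacts.tsv", "segment")
    ref_path = Path(
        cfg.reference_contacts or Path(cfg.output_dir) / "phantom" / "truth.tsv"
    )
    _require(ref_path, "phantom")
    auto = pd.read_csv(auto_path, sep="\t")[["x_mm", "y_mm", "z_mm"]].to_numpy()
    ref = pd.read_csv(ref_path, sep="\t")[["x_mm", "y_mm", "z_mm"]].to_numpy()
    report = match_contacts(auto, ref)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    report.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    _write_manifest(out, "validate", cfg, report.to_dict())
    return out


STAGES = {
    "phantom": run_phantom,
    "segment": run_segment,
    "electrodes": run_electrodes,
    "signal": run_signal,
    "animate": run_animate,
    "validate": run_validate,
}


def run_all(cfg: PipelineConfig) -> list[Path]:
    return [STAGES[name](cfg) for name in
            ("phantom", "segment", "electrodes", "signal", "animate", "validate")]
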