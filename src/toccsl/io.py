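"""Configuration, TIFF/CSV/YAML input-output and provenance.

A single YAML file configures both simulation and analysis. Parsing is strict:
unknown keys are errors, every run's output embeds the resolved configuration
hash, seed and package version. Image stacks are multi-page TIFF with a YAML
sidecar carrying the protocol descriptor (timings in ms, ROI in um, seed, all
parameters); ground truth goes to CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .params import ImagingParams, PhotophysicsParams, ProtocolTiming, Rect, SceneParams
from .protocol import AnalysisSettings
from .spots import FilterCriteria
from .synthetic import ToccslRun

__all__ = [
    "AnalysisConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_hash",
    "save_run",
    "load_run",
    "write_manifest",
    "provenance",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content, with the offending field."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved configuration for simulation and analysis."""

    scene: SceneParams = field(default_factory=SceneParams)
    photophysics: PhotophysicsParams = field(default_factory=PhotophysicsParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    frap_noise_sd: float = 0.02
    frap_recovery_rate: float = 0.2
    monomer_calibration_frames: int = 25
    monomer_calibration_density: float = 0.08
    seed: int = 0


# --- generic strict dataclass <-> plain-dict conversion ---------------------


def _encode(value):
    if isinstance(value, Rect):
        return [value.x0, value.y0, value.x1, value.y1]
    if is_dataclass(value) and not isinstance(value, type):
        return {f.name: _encode(getattr(value, f.name)) for f in fields(value)}
    if isinstance(value, (tuple, list, np.ndarray)):
        return [_encode(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def _decode(cls, data, path="config"):
    if cls is Rect:
        if not (isinstance(data, (list, tuple)) and len(data) == 4):
            raise ConfigError(f"{path}: a rectangle needs [x0, y0, x1, y1]")
        return Rect(*map(float, data))
    if is_dataclass(cls):
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        kwargs = {}
        for name, f in known.items():
            if name not in data:
                continue
            ftype = f.type if isinstance(f.type, type) else _resolve_type(f)
            try:
                kwargs[name] = _decode(ftype, data[name], f"{path}.{name}")
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ConfigError):
                    raise
                raise ConfigError(f"{path}.{name}: {exc}") from exc
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    if cls is float:
        return float(data)
    if cls is int:
        if isinstance(data, float) and not data.is_integer():
            raise ConfigError(f"{path}: expected an integer, got {data}")
        return int(data)
    if cls is bool:
        return bool(data)
    if cls is tuple:
        return tuple(float(v) for v in data)
    return data


_TYPE_NAMES = {
    "float": float,
    "int": int,
    "bool": bool,
    "str": str,
    "Rect": Rect,
    "SceneParams": SceneParams,
    "PhotophysicsParams": PhotophysicsParams,
    "ImagingParams": ImagingParams,
    "ProtocolTiming": ProtocolTiming,
    "AnalysisSettings": AnalysisSettings,
    "FilterCriteria": FilterCriteria,
}


def _resolve_type(f: dataclasses.Field):
    name = f.type if isinstance(f.type, str) else getattr(f.type, "__name__", "")
    if name.startswith("tuple"):
        return tuple
    return _TYPE_NAMES.get(name, None.__class__)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _decode(AnalysisConfig, data)


def config_to_dict(config: AnalysisConfig) -> dict:
    return _encode(config)


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: AnalysisConfig) -> dict:
    return {
        "package": "toccsl",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
    }


# --- runs --------------------------------------------------------------------


def save_run(run: ToccslRun, directory, name: str, extra_meta: dict | None = None) -> list[Path]:
    """Write a run as <name>.tif (pages in FRAME_ORDER), sidecar YAML, truth CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    stack = np.stack([run.frames[k] for k in ToccslRun.FRAME_ORDER]).astype(np.float32)
    tif_path = directory / f"{name}.tif"
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    written.append(tif_path)
    meta = {
        "frames": list(ToccslRun.FRAME_ORDER),
        "timing": _encode(run.timing),
        "roi": _encode(run.roi),
        "imaging": _encode(run.imaging),
        "field_size": list(run.field_size),
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = directory / f"{name}.yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    written.append(sidecar)
    for frame_name, table in run.truth.items():
        p = directory / f"{name}_truth_{frame_name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    return written


def load_run(directory, name: str) -> ToccslRun:
    directory = Path(directory)
    with open(directory / f"{name}.yaml") as fh:
        meta = yaml.safe_load(fh)
    stack = tifffile.imread(directory / f"{name}.tif").astype(float)
    frames = {k: stack[i] for i, k in enumerate(meta["frames"])}
    truth = {}
    for frame_name in meta["frames"]:
        p = directory / f"{name}_truth_{frame_name}.csv"
        if p.exists():
            truth[frame_name] = pd.read_csv(p)
    return ToccslRun(
        frames=frames,
        timing=_decode(ProtocolTiming, meta["timing"], "timing"),
        roi=_decode(Rect, meta["roi"], "roi"),
        imaging=_decode(ImagingParams, meta["imaging"], "imaging"),
        field_size=tuple(meta["field_size"]),
        truth=truth,
    )


def write_manifest(directory, config: AnalysisConfig) -> Path:
    """Checksummed listing of every file in a fixture bundle."""
    directory = Path(directory)
    entries = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(directory))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"provenance": provenance(config), "files": entries}
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
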