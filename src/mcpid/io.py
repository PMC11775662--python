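"""Serialization: configs, run manifests and report files."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import ConsortiumParams, ControlGains

__all__ = [
    "load_config",
    "save_config",
    "write_json",
    "write_manifest",
    "params_to_dict",
]


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _coerce(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _coerce(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_coerce(v) for v in obj]
    return obj


def params_to_dict(params: ConsortiumParams, gains: ControlGains | None = None) -> dict:
    d = _coerce(params)
    if gains is not None:
        d.update(_coerce(gains))
    return d


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    return doc


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_coerce(config), fh, sort_keys=True)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_coerce(obj), fh, indent=2)
        fh.write("\n")


def write_manifest(out_dir, command: str, config: dict, seed, outputs) -> Path:
    """Record what was run, with what, and where the outputs went."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": _coerce(config),
        "seed": seed,
        "version": __version__,
        "outputs": [str(p) for p in outputs],
        "written_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path
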