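"""Shared readers/writers and configuration handling.

Formats: TIFF for images and field snapshots (via tifffile), CSV for
profiles/tracks/reports (via pandas), YAML for parameter files, JSON for
structured reports. Every run driven through the CLI writes a resolved copy
of its configuration next to its outputs so defaults are auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed YAML in {path}: {e}") from e
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def build_params(cls, cfg: dict):
    """Instantiate a parameter dataclass from a config mapping, rejecting
    unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; known: {sorted(known)}"
        )
    return cls(**cfg)


def write_resolved_config(obj, out_dir: str | Path, name: str = "resolved_config.json") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = dataclasses.asdict(obj)
    else:
        payload = obj
    (out_dir / name).write_text(json.dumps(payload, indent=2, default=str))


def save_field_stack(
    stacks: dict[str, list[np.ndarray]],
    times: list[float],
    out_dir: str | Path,
) -> None:
    """Write one multi-page TIFF per field plus a CSV manifest
    (page, t, max, mean per field)."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, frames in stacks.items():
        arr = np.stack(frames).astype(np.float32)
        tifffile.imwrite(out_dir / f"{name}.tif", arr)
        for i, (t, frame) in enumerate(zip(times, frames)):
            rows.append(
                {
                    "field": name,
                    "page": i,
                    "t": t,
                    "max": float(frame.max()),
                    "mean": float(frame.mean()),
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)


def write_profile_csv(profile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)


def write_wave_track_csv(track, path: str | Path) -> None:
    frame = track.to_frame()
    frame.attrs = {}
    frame.to_csv(path, index=False)
    meta = {
        "threshold": track.threshold,
        "slope_um_per_h": track.slope,
        "intercept_um": track.intercept,
        "r_squared": track.r_squared,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
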