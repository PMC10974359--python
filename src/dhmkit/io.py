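"""File I/O: float TIFF / NPY images, YAML sidecars, deterministic JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from dhmkit.simulate import Hologram, OpticalConstants, SimConfig

__all__ = [
    "save_image",
    "load_image",
    "save_hologram",
    "load_hologram",
    "save_json_report",
    "load_config",
]


def save_image(path: str | Path, array: np.ndarray) -> Path:
    """Write a 2D array as 32-bit float TIFF or NPY, by extension."""
    path = Path(path)
    arr = np.asarray(array, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".npy":
        np.save(path, arr)
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r} (use .tif/.tiff/.npy)")
    return path


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    if path.suffix.lower() == ".npy":
        return np.asarray(np.load(path), dtype=float)
    raise ValueError(f"unsupported image extension {path.suffix!r}")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_hologram(directory: str | Path, hologram: Hologram, stem: str) -> dict:
    """Write intensity as TIFF + NPY with a YAML sidecar of the metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": save_image(directory / f"{stem}.tiff", hologram.intensity),
        "npy": save_image(directory / f"{stem}.npy", hologram.intensity),
    }
    sidecar = {
        "kind": hologram.kind,
        "constants": _to_plain(hologram.constants) if hologram.constants else None,
        "config": _to_plain(hologram.config) if hologram.config else None,
    }
    yaml_path = directory / f"{stem}.yaml"
    yaml_path.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    paths["yaml"] = yaml_path
    return paths


def load_hologram(image_path: str | Path) -> Hologram:
    """Load a hologram image; picks up a matching YAML sidecar if present."""
    image_path = Path(image_path)
    intensity = load_image(image_path)
    constants = config = None
    kind = "object"
    sidecar = image_path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        kind = meta.get("kind", "object")
        if meta.get("constants"):
            constants = OpticalConstants(**meta["constants"])
        if meta.get("config"):
            cfg = dict(meta["config"])
            cfg["carrier"] = tuple(cfg["carrier"])
            cfg["shape"] = tuple(cfg["shape"])
            config = SimConfig(**cfg)
    return Hologram(intensity, constants=constants, config=config, kind=kind)


def save_json_report(path: str | Path, payload: dict) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(_to_plain(payload), sort_keys=True, indent=2)
    path.write_text(text + "\n")
    return path


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration."""
    return yaml.safe_load(Path(path).read_text()) or {}
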