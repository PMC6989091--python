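"""Shared file I/O: TIFF stacks with metadata sidecars, config, manifests."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "load_config",
    "write_manifest",
    "model_params_from_config",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: np.ndarray, path, metadata: dict | None = None) -> None:
    """Write a (t, y, x) stack as multi-page TIFF with a JSON sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (t, y, x)")
    tifffile.imwrite(path, stack.astype(np.float32), metadata={"axes": "TYX"})
    if metadata:
        _sidecar_path(path).write_text(json.dumps(metadata, indent=1, sort_keys=True))


def read_stack(path, require_metadata: bool = False):
    """Read a multi-page TIFF (axes TYX) and its sidecar metadata.

    Returns (stack, metadata).  When ``require_metadata`` is set, a missing
    sidecar (or one without ``pixel_size_um``) raises instead of returning
    an empty dict — pass the values explicitly if no sidecar exists.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"ambiguous axis order for {stack.ndim}D stack; expected TYX"
        )
    side = _sidecar_path(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if require_metadata and "pixel_size_um" not in meta:
        raise ValueError(
            f"no pixel size for {path}: provide a {side.name} sidecar or flags"
        )
    return stack, meta


def load_config(path) -> dict:
    """Load a YAML config with per-subcommand sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def model_params_from_config(cfg: dict):
    """Build ModelParams from config keys (units embedded in key names)."""
    from .hydro import ModelParams

    d = float(cfg["d_um"]) * 1e-6
    h = float(cfg.get("h_frac", 0.5)) * d
    fv = cfg.get("fv_n_per_m3")
    return ModelParams(
        mu=float(cfg.get("mu", 1e-3)),
        d=d,
        h=h,
        alpha=float(cfg.get("alpha", 0.5)),
        f=float(cfg.get("f_hz", 40.0)),
        fv=float(fv) if fv is not None else None,
    )


def write_manifest(out_dir, subcommand: str, params: dict, seed=None) -> Path:
    """Write a reproducibility manifest (config + versions + seed)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _clean(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    manifest = {
        "subcommand": subcommand,
        "seed": seed,
        "params": _clean(params),
        "versions": {
            "cilioflow": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
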