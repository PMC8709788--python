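"""Shared readers/writers and YAML-driven reproducible runs.

Stacks travel as multi-page TIFF with a declared axes specification
(``"TYX"`` for 3D, ``"TYXC"`` for spectral 4D) plus a YAML sidecar carrying
metadata (timestamps, channel codes, ground truth).  Plate tables are CSV.
``run_config`` executes one of the package's recovery protocols from a
single YAML file, logging seed, versions and parameters for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "read_sidecar",
    "ConfigError",
    "run_config",
]

_AXES = {"TYX": 3, "TYXC": 4, "YX": 2, "ZYX": 3}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _plain(obj):
    """Recursively convert numpy/dataclass values into YAML-safe types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_stack(stack: np.ndarray, path: str | Path, axes_spec: str,
                metadata: dict | None = None) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar.

    Integer photon counts round-trip losslessly (the dtype is preserved).
    """
    if axes_spec not in _AXES:
        raise ValueError(f"unknown axes_spec {axes_spec!r}; "
                         f"one of {sorted(_AXES)}")
    arr = np.asarray(stack)
    if arr.ndim != _AXES[axes_spec]:
        raise ValueError(f"axes_spec {axes_spec!r} expects "
                         f"{_AXES[axes_spec]}D data, got {arr.ndim}D")
    path = Path(path)
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = {"axes": axes_spec, "shape": list(arr.shape),
               "dtype": str(arr.dtype)}
    if metadata:
        sidecar["metadata"] = _plain(metadata)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return path


def read_stack(path: str | Path, axes_spec: str) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack, validating axes against the declared spec."""
    if axes_spec not in _AXES:
        raise ValueError(f"unknown axes_spec {axes_spec!r}")
    path = Path(path)
    arr = tifffile.imread(path)
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
        declared = meta.get("axes")
        if declared is not None and declared != axes_spec:
            raise ValueError(f"stack was written with axes {declared!r}, "
                             f"requested {axes_spec!r}")
    if arr.ndim != _AXES[axes_spec]:
        raise ValueError(f"axes_spec {axes_spec!r} expects "
                         f"{_AXES[axes_spec]}D data, got {arr.ndim}D")
    return arr, meta.get("metadata", {})


def read_sidecar(path: str | Path) -> dict:
    with open(_sidecar_path(Path(path))) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# YAML-driven runs
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Raised when a run configuration is missing or misusing keys."""


_TASKS = ("ec50_recovery", "t75_recovery", "binding_recovery")


def run_config(config_path: str | Path,
               out_path: str | Path | None = None) -> dict:
    """Execute a recovery protocol described by a YAML configuration.

    Schema::

        task: ec50_recovery | t75_recovery | binding_recovery
        seed: <int>                  # master seed for all randomness
        params: {...}                # forwarded to the protocol function
        out: results.json            # optional, overridden by out_path

    The output JSON contains the result plus a provenance block (task,
    seed, parameters, package and numpy versions).  Identical config and
    seed reproduce identical outputs.
    """
    from . import __version__, recovery

    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run configuration must be a mapping")
    for key in ("task", "seed"):
        if key not in cfg:
            raise ConfigError(f"missing required config key: {key!r}")
    task = cfg["task"]
    if task not in _TASKS:
        raise ConfigError(f"unknown task {task!r}; one of {_TASKS}")
    seed = int(cfg["seed"])
    params = cfg.get("params", {}) or {}
    if not isinstance(params, dict):
        raise ConfigError("config key 'params' must be a mapping")

    func = {"ec50_recovery": recovery.recover_ec50,
            "t75_recovery": recovery.recover_t75,
            "binding_recovery": recovery.recover_binding_efficiency}[task]
    result = func(seed=seed, **params)
    payload = {
        "task": task,
        "result": _plain(result),
        "provenance": {
            "seed": seed,
            "params": _plain(params),
            "cipkit_version": __version__,
            "numpy_version": np.__version__,
        },
    }
    target = Path(out_path) if out_path is not None else (
        config_path.parent / cfg["out"] if "out" in cfg else None)
    if target is not None:
        with open(target, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
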