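"""NIfTI / CSV / JSON / YAML plumbing shared by the pipeline and the CLI.

Volumes are written in RAS orientation with an identity rotation and the
voxel spacing on the affine diagonal; coordinates in CLI flags are 0-based
voxel indices.  Masks round-trip losslessly as uint8; maps as float32.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_json",
    "load_json",
    "save_table",
    "load_table",
    "load_config",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, array: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(dtype=np.float32)), spacing


def save_mask(path, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    arr, spacing = load_volume(path)
    return arr.astype(np.uint8).astype(bool), spacing


def save_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")


def load_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"JSON file not found: {path}")
    return json.loads(path.read_text())


def save_table(path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def load_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    return pd.read_csv(path)


def load_config(path, required: tuple[str, ...] = ()) -> dict:
    """Read a YAML or JSON configuration file, checking required keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    for key in required:
        if key not in cfg:
            raise KeyError(f"config file {path} is missing required key {key!r}")
    return cfg
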