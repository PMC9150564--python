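"""NIfTI / CSV / JSON input-output helpers.

Volumes are written as single-slice NIfTI with an RAS+ affine whose voxel
sizes come from the grid (mm); complex fields are split into real and
imaginary volumes.  Every study writes a JSON provenance sidecar carrying
the seed, parameters and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import GridSpec

__all__ = ["save_map", "load_map", "save_complex", "load_complex", "write_sidecar"]


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = grid.dx * 1e3
    aff[1, 1] = grid.dy * 1e3
    aff[2, 2] = 5.0  # nominal slice thickness, mm
    return aff


def save_map(arr: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    """Write a real 2-D map as a single-slice NIfTI volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64)[..., None], _affine(grid))
    nib.save(img, str(path))
    return path


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())[..., 0]


def save_complex(arr: np.ndarray, grid: GridSpec, stem: str | Path) -> tuple[Path, Path]:
    """Write a complex map as ``<stem>_real.nii.gz`` and ``<stem>_imag.nii.gz``."""
    stem = Path(stem)
    return (
        save_map(np.real(arr), grid, stem.parent / f"{stem.name}_real.nii.gz"),
        save_map(np.imag(arr), grid, stem.parent / f"{stem.name}_imag.nii.gz"),
    )


def load_complex(stem: str | Path) -> np.ndarray:
    stem = Path(stem)
    return load_map(stem.parent / f"{stem.name}_real.nii.gz") + 1j * load_map(
        stem.parent / f"{stem.name}_imag.nii.gz"
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_sidecar(path: str | Path, **payload) -> Path:
    """Write a JSON provenance sidecar (seeds, parameters, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(payload)
    payload["config_hash"] = config_hash(payload)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
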