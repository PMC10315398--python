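"""NIfTI / CSV / JSON artifact writing with provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np


def write_nifti(path: Path, array: np.ndarray, voxel_size: float = 0.5) -> Path:
    """Write an array as NIfTI-1 with an isotropic affine (mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))
    return path


def read_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_json(path: Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: Path, config: dict, seed: int, stage: str) -> Path:
    """Provenance sidecar: configuration hash, seed, and stage name."""
    from . import __version__

    return write_json(
        Path(path),
        {
            "stage": stage,
            "seed": seed,
            "config_hash": config_hash(config),
            "version": __version__,
        },
    )
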