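"""NIfTI, YAML and JSON input/output.

Volumes are written as NIfTI with a diagonal affine carrying the isotropic
spacing; masks as uint8.  Scene specs and configs round-trip through YAML,
and every simulation records its seeds in a JSON sidecar so reruns are
bit-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigurationError
from .grid import VolumeGrid

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_mask",
    "read_mask",
    "load_yaml",
    "dump_yaml",
    "write_json",
    "read_json",
]


def write_nifti(grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag([grid.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = grid.origin_mm
    img = nib.Nifti1Image(grid.values.astype(np.float32), affine)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    affine = img.affine
    spacings = np.abs(np.diag(affine)[:3])
    if not np.allclose(spacings, spacings[0], rtol=1e-4):
        raise ConfigurationError(f"{path}: anisotropic voxels are not supported")
    data = np.asanyarray(img.dataobj).astype(float)
    return VolumeGrid(data, float(spacings[0]), affine[:3, 3].copy())


def write_mask(mask: np.ndarray, like: VolumeGrid, path: str | Path) -> Path:
    return write_nifti(like.copy(values=mask.astype(np.uint8)), path)


def read_mask(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    grid = read_nifti(path)
    return grid.values > 0.5, grid


def load_yaml(path: str | Path) -> Any:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
    return path


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
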