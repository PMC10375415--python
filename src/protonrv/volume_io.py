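"""NRRD volume persistence (via SimpleITK) and small JSON/CSV helpers.

Grids are stored with our [ix, iy, iz] axis order mapped to the NRRD
(x, y, z) axes, with voxel spacing and origin in the header, so a
write/read round trip is bit-identical for float and integer grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["write_volume", "read_volume", "write_json", "read_json"]


def write_volume(path, grid: np.ndarray, voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write a 3D grid indexed [ix, iy, iz] to an NRRD file."""
    grid = np.ascontiguousarray(np.transpose(grid, (2, 1, 0)))  # sitk wants (z, y, x)
    img = sitk.GetImageFromArray(grid)
    img.SetSpacing(tuple(float(v) for v in np.broadcast_to(voxel_size_mm, (3,))))
    img.SetOrigin(tuple(float(v) for v in origin_mm))
    sitk.WriteImage(img, str(path))


def read_volume(path):
    """Read an NRRD file; returns (grid [ix, iy, iz], voxel_size_mm, origin_mm)."""
    img = sitk.ReadImage(str(path))
    grid = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return grid, np.array(img.GetSpacing()), np.array(img.GetOrigin())


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
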