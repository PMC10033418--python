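"""Volume and table I/O.

Multi-page TIFF is the primary interchange format for volumes (one page per
z-slice); MRC volumes are supported read-only via gemmi.  TIFF tags are not
trusted for the section spacing — the physical voxel size always comes from
the caller or a config.  Tables travel as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .grids import VolumeGrid

__all__ = ["read_volume", "write_volume"]


def write_volume(path, grid: VolumeGrid) -> None:
    """Write a volume as a multi-page TIFF (one page per z-slice)."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(f"write_volume writes TIFF only, got {path.suffix!r}")
    tifffile.imwrite(path, np.asarray(grid.data))


def read_volume(path, voxel_size=(50.0, 5.0, 5.0), fmt: str | None = None) -> VolumeGrid:
    """Read a multi-page TIFF or MRC volume into a (z, y, x) grid.

    ``fmt`` is inferred from the suffix when omitted ("tiff" or "mrc").
    ``voxel_size`` (dz, dy, dx in nm) is attached as given.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".tif": "tiff", ".tiff": "tiff", ".mrc": "mrc", ".rec": "mrc",
               ".map": "mrc"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer volume format from suffix {suffix!r}")
    if fmt == "tiff":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got ndim={data.ndim}")
    elif fmt == "mrc":
        data = _read_mrc(path)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return VolumeGrid(data, voxel_size)


def _read_mrc(path) -> np.ndarray:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    # gemmi grids are (nx, ny, nz) fastest-first; present as (z, y, x)
    arr = np.array(m.grid, copy=True)
    return np.transpose(arr, (2, 1, 0))
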