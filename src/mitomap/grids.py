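"""Anisotropic 3D volume container.

Volume EM stacks are sampled much more finely in-plane than axially (here
5-6 nm laterally vs a 50 nm section thickness), so every physical
measurement must carry the per-axis voxel size.  ``VolumeGrid`` is the
substrate used by all raster operations in this package: arrays are indexed
``(z, y, x)``, 0-based, and the physical coordinate of the *center* of voxel
``(k, j, i)`` is ``origin + (k*dz, j*dy, i*dx)`` in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGrid", "NM_PER_UM", "voxel_volume_um3"]

NM_PER_UM = 1000.0


@dataclass
class VolumeGrid:
    """A 3D scalar or label field with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar (grayscale) or integer (mask / label) values.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in nanometres; all strictly positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in nanometres, ``(z, y, x)`` order.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (50.0, 5.0, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid expects a 3D array, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical (z, y, x) coordinates (nm) of voxel index rows (k, j, i)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this grid's geometry."""
        return VolumeGrid(data, self.voxel_size, self.origin)


def voxel_volume_um3(voxel_size: tuple[float, float, float]) -> float:
    """Volume of one voxel in cubic micrometres given (dz, dy, dx) in nm."""
    dz, dy, dx = voxel_size
    return dz * dy * dx / NM_PER_UM**3
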