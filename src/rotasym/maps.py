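"""Voxel-grid density maps with a physical voxel size.

Conventions used throughout the package:

* the grid is indexed ``[z, y, x]`` (section, row, column), the common order
  for electron-microscopy volumes in Python;
* the cyclic-symmetry axis is +z and passes through the geometric centre of
  the grid, which sits at voxel coordinate ``(n - 1) / 2`` along each axis;
* axes are right-handed and azimuthal angles are measured counter-clockwise
  when viewed from +z;
* all physical map lengths are in ångström (Å).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DensityMap"]


@dataclass(frozen=True)
class DensityMap:
    """A 3D scalar density on a cubic-voxel grid.

    Parameters
    ----------
    grid:
        Density values, indexed ``[z, y, x]``, arbitrary units.
    voxel_size:
        Isotropic voxel edge length in Å.
    """

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got {grid.ndim}D")
        if min(grid.shape) < 8:
            raise ValueError(f"grid dimensions must be >= 8, got {grid.shape}")
        if not np.isfinite(grid).all():
            raise ValueError("grid contains non-finite values")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def centre(self) -> np.ndarray:
        """Grid centre in voxel coordinates, order (z, y, x)."""
        return (np.array(self.shape, dtype=float) - 1.0) / 2.0

    def total_density(self) -> float:
        """Integral of the map in density·Å³ (voxel sum × voxel volume)."""
        return float(self.grid.sum() * self.voxel_size**3)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical (z, y, x) coordinates in Å of every voxel, origin at centre.

        Returned as three broadcastable 1D arrays shaped for ``[z, y, x]``
        indexing, so memory stays O(n) rather than O(n³).
        """
        nz, ny, nx = self.shape
        cz, cy, cx = self.centre
        z = (np.arange(nz) - cz)[:, None, None] * self.voxel_size
        y = (np.arange(ny) - cy)[None, :, None] * self.voxel_size
        x = (np.arange(nx) - cx)[None, None, :] * self.voxel_size
        return z, y, x

    def radial_extent(self) -> float:
        """Largest radius (Å) from the symmetry axis contained in the xy plane."""
        nz, ny, nx = self.shape
        return float(min(nx - 1, ny - 1) / 2.0 * self.voxel_size)

    def with_grid(self, grid: np.ndarray) -> "DensityMap":
        return DensityMap(grid=grid, voxel_size=self.voxel_size)
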