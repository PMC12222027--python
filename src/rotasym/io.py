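"""Reading and writing the package's on-disk formats.

Maps travel as MRC2014/CCP4 mode-2 (32-bit float) volumes with the voxel
size recorded in the cell parameters; bead trajectories as CSV with header
``t,x,y`` (seconds, nm).  Both round-trip losslessly at the stated
precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .maps import DensityMap
from .steps import BeadTrajectory

__all__ = ["read_map", "write_map", "read_trajectory", "write_trajectory"]

logger = logging.getLogger(__name__)

_MRC_MODE_FLOAT32 = 2


def write_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014 mode 2 (32-bit float).

    The grid is stored x-fastest; the voxel size goes into the unit-cell
    parameters (cell edge = dimension × voxel size).
    """
    nz, ny, nx = density_map.shape
    vs = density_map.voxel_size
    grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.grid.T, dtype=np.float32))
    grid.unit_cell = gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC2014/CCP4 mode-2 map.

    Only mode 2 (32-bit float) with isotropic voxels is supported; other
    modes, anisotropic voxel sizes, and truncated files raise ``ValueError``
    naming the problem.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, SystemError) as exc:
        raise ValueError(f"cannot read map {path}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode != _MRC_MODE_FLOAT32:
        raise ValueError(
            f"unsupported MRC mode {mode} in {path}; only mode {_MRC_MODE_FLOAT32} "
            "(32-bit float) is supported"
        )
    spacing = ccp4.grid.spacing
    if max(spacing) - min(spacing) > 1e-3 * max(spacing):
        raise ValueError(
            f"anisotropic voxel size {tuple(round(s, 4) for s in spacing)} Å in {path} "
            "is not supported"
        )
    data = np.array(ccp4.grid, copy=True)  # (x, y, z) order
    return DensityMap(grid=np.ascontiguousarray(data.T, dtype=np.float64),
                      voxel_size=float(np.mean(spacing)))


def write_trajectory(traj: BeadTrajectory, path: str | Path) -> None:
    """Write a bead trajectory as CSV with header ``t,x,y``, 9 significant digits."""
    frame = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    frame.to_csv(path, index=False, float_format="%.9g")


def read_trajectory(path: str | Path) -> BeadTrajectory:
    """Read a ``t,x,y`` CSV trajectory (seconds, nm).

    Extra columns are ignored with a warning; missing columns, non-numeric
    rows (reported with their line numbers) and non-monotone timestamps are
    errors.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ("t", "x", "y") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; need header t,x,y")
    extra = [c for c in frame.columns if c not in ("t", "x", "y")]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, extra)
    values = frame[["t", "x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        lines = (values.index[bad] + 2).tolist()
        raise ValueError(f"{path}: non-numeric value(s) on line(s) {lines[:20]}")
    t = values["t"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    return BeadTrajectory(t=t, x=values["x"].to_numpy(), y=values["y"].to_numpy())
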