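"""Synthetic density phantoms for ring-shaped protein assemblies.

These generators produce the idealized geometries the analysis modules are
designed to measure: rings of Gaussian subunits (C-ring, basal-disk rings),
multi-ring concentric disks, and azimuthally uniform cylindrical shells
(the FliF β-collar).  They exist so that every downstream operation —
symmetry detection, lathing, radial profiling, FSC — can be exercised on
inputs with exactly known ground truth.

All phantoms are deterministic; :func:`make_half_maps` is the only stochastic
operation and is a pure function of ``(map, snr, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disk import DiskLatticeModel, ring_protomer_counts, ring_radii
from .maps import DensityMap

__all__ = [
    "RingPhantomSpec",
    "make_ring_phantom",
    "make_concentric_disk_phantom",
    "make_cylinder_phantom",
    "make_half_maps",
]

# Gaussian blobs are truncated at 4 sigma: beyond that the density is below
# 3.4e-4 of the peak, negligible against the 1% integral tolerances used here,
# and truncation keeps phantom construction O(blobs * sigma^3) not O(grid^3).
_BLOB_CUTOFF_SIGMAS = 4.0


@dataclass(frozen=True)
class RingPhantomSpec:
    """Geometry of a ring of identical isotropic Gaussian subunits.

    ``n_subunits`` blob centres sit at radius ``ring_radius`` (Å) from the z
    axis, at angles ``phase0 + 2*pi*j/n_subunits``, all at height ``z_offset``
    (Å) from the grid centre.  Overlapping blobs are allowed.
    """

    n_subunits: int
    ring_radius: float
    subunit_sigma: float
    z_offset: float = 0.0
    amplitude: float = 1.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if not (self.ring_radius > 0):
            raise ValueError("ring_radius must be > 0")
        if not (self.subunit_sigma > 0):
            raise ValueError("subunit_sigma must be > 0")


def _empty_map(grid_shape: tuple[int, int, int], voxel_size: float) -> DensityMap:
    return DensityMap(grid=np.zeros(grid_shape, dtype=np.float64), voxel_size=voxel_size)


def _check_ring_fits(radius: float, sigma: float, phantom: DensityMap) -> None:
    extent = phantom.radial_extent()
    needed = radius + _BLOB_CUTOFF_SIGMAS * sigma
    if needed > extent:
        raise ValueError(
            f"ring does not fit in grid: radius {radius:g} Å + "
            f"{_BLOB_CUTOFF_SIGMAS:g}σ ({_BLOB_CUTOFF_SIGMAS * sigma:g} Å) exceeds the "
            f"half-extent {extent:g} Å of the xy plane"
        )


def _add_gaussian_blob(
    phantom: DensityMap,
    centre_xyz: tuple[float, float, float],
    sigma: float,
    amplitude: float,
) -> None:
    """Accumulate one isotropic Gaussian (truncated at 4σ) into the grid in place."""
    nz, ny, nx = phantom.shape
    vs = phantom.voxel_size
    cz, cy, cx = phantom.centre  # voxel coords of physical origin
    x0, y0, z0 = centre_xyz
    # blob centre in voxel coordinates
    vz, vy, vx = z0 / vs + cz, y0 / vs + cy, x0 / vs + cx
    half = _BLOB_CUTOFF_SIGMAS * sigma / vs
    iz0, iz1 = max(0, int(np.floor(vz - half))), min(nz, int(np.ceil(vz + half)) + 1)
    iy0, iy1 = max(0, int(np.floor(vy - half))), min(ny, int(np.ceil(vy + half)) + 1)
    ix0, ix1 = max(0, int(np.floor(vx - half))), min(nx, int(np.ceil(vx + half)) + 1)
    if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
        return
    dz = (np.arange(iz0, iz1) - vz)[:, None, None] * vs
    dy = (np.arange(iy0, iy1) - vy)[None, :, None] * vs
    dx = (np.arange(ix0, ix1) - vx)[None, None, :] * vs
    r2 = dz * dz + dy * dy + dx * dx
    phantom.grid[iz0:iz1, iy0:iy1, ix0:ix1] += amplitude * np.exp(-r2 / (2.0 * sigma**2))


def make_ring_phantom(
    spec: RingPhantomSpec,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
) -> DensityMap:
    """Build a map that is a sum of ``n_subunits`` Gaussians on a ring.

    The result has exact n-fold rotational symmetry about z up to grid
    discretisation.  Raises ``ValueError`` if the ring (plus the 4σ blob
    support) does not fit inside the grid.
    """
    phantom = _empty_map(grid_shape, voxel_size)
    _check_ring_fits(spec.ring_radius, spec.subunit_sigma, phantom)
    angles = spec.phase0 + 2.0 * np.pi * np.arange(spec.n_subunits) / spec.n_subunits
    for a in angles:
        centre = (
            spec.ring_radius * np.cos(a),
            spec.ring_radius * np.sin(a),
            spec.z_offset,
        )
        _add_gaussian_blob(phantom, centre, spec.subunit_sigma, spec.amplitude)
    return phantom


def make_concentric_disk_phantom(
    model: DiskLatticeModel,
    subunit_sigma: float,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    amplitude: float = 1.0,
    z_offset: float = 0.0,
) -> DensityMap:
    """Multi-ring disk phantom following a concentric-ring lattice model.

    Ring *i* carries the protomer count the lattice model assigns it, one
    Gaussian blob per protomer.  Successive rings get a small deterministic
    phase offset so that only the innermost ring is guaranteed to share the
    global n1-fold symmetry — mirroring a disk whose outer rings are not in
    rotational register with the first.
    """
    phantom = _empty_map(grid_shape, voxel_size)
    radii = ring_radii(model)
    counts = ring_protomer_counts(model)
    _check_ring_fits(float(radii[-1]), subunit_sigma, phantom)
    for i, (radius, count) in enumerate(zip(radii, counts)):
        # incommensurate per-ring phase so outer rings break global symmetry
        phase = 0.0 if i == 0 else 0.5 * i
        spec = RingPhantomSpec(
            n_subunits=int(count),
            ring_radius=float(radius),
            subunit_sigma=subunit_sigma,
            z_offset=z_offset,
            amplitude=amplitude,
            phase0=phase,
        )
        ring = make_ring_phantom(spec, grid_shape, voxel_size)
        phantom.grid[...] += ring.grid
    return phantom


def make_cylinder_phantom(
    radius: float,
    height: float,
    wall_sigma: float,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    amplitude: float = 1.0,
) -> DensityMap:
    """Azimuthally uniform cylindrical shell (a lathed ring such as a β-collar).

    Density is a Gaussian in cylindrical radius centred on ``radius``,
    uniform in azimuth, and a boxcar of extent ``height`` in z, all in Å.
    """
    if not (radius > 0 and height > 0 and wall_sigma > 0):
        raise ValueError("radius, height and wall_sigma must all be > 0")
    phantom = _empty_map(grid_shape, voxel_size)
    extent = phantom.radial_extent()
    if radius + _BLOB_CUTOFF_SIGMAS * wall_sigma > extent:
        raise ValueError(
            f"cylinder does not fit in grid: radius {radius:g} Å + "
            f"{_BLOB_CUTOFF_SIGMAS:g}σ exceeds the half-extent {extent:g} Å"
        )
    z, y, x = phantom.coordinate_grids()
    r = np.hypot(x, y)
    radial = np.exp(-((r - radius) ** 2) / (2.0 * wall_sigma**2))
    axial = (np.abs(z) <= height / 2.0).astype(np.float64)
    phantom.grid[...] = amplitude * radial * axial
    return phantom


def make_half_maps(
    density_map: DensityMap, snr: float, seed: int
) -> tuple[DensityMap, DensityMap]:
    """Two noisy copies of a map with independent white-Gaussian noise.

    The noise standard deviation is chosen so that the ratio of the signal
    voxel variance to the noise variance equals ``snr``, emulating a pair of
    gold-standard half-maps reconstructed from independent particle halves.
    Real reconstruction noise is frequency-structured; white noise is enough
    to exercise FSC machinery with a known answer.  ``snr=inf`` adds no
    noise at all, so the two half-maps are identical and their FSC is 1 in
    every shell.
    """
    if not (snr > 0):
        raise ValueError("snr must be > 0")
    if np.isinf(snr):
        return density_map.with_grid(density_map.grid.copy()), density_map.with_grid(
            density_map.grid.copy()
        )
    signal_var = float(np.var(density_map.grid))
    noise_sd = np.sqrt(signal_var / snr)
    rng = np.random.default_rng(seed)
    noise_a = rng.standard_normal(density_map.shape) * noise_sd
    noise_b = rng.standard_normal(density_map.shape) * noise_sd
    return (
        density_map.with_grid(density_map.grid + noise_a),
        density_map.with_grid(density_map.grid + noise_b),
    )
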