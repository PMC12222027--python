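"""Radial density profiles of cylindrically organised maps.

Used to measure ring radii (L- and P-rings, the FliF β-collar) and to
compare ring widths between motors: the density is averaged over azimuth and
over a slab in z, binned by distance from the symmetry axis, and the peak
radius is located with sub-voxel (parabolic) precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import DensityMap

__all__ = ["RadialProfile", "radial_density_profile", "peak_radius"]


@dataclass(frozen=True)
class RadialProfile:
    """Mean density per radial bin; radii are bin centres in Å."""

    radii: np.ndarray
    mean_density: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        dens = np.asarray(self.mean_density, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "mean_density", dens)
        if radii.shape != dens.shape or radii.ndim != 1:
            raise ValueError("radii and mean_density must be 1D of equal length")
        if np.any(radii < 0) or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be non-negative and increasing")


def radial_density_profile(
    density_map: DensityMap, z_band: tuple[float, float] | None = None
) -> RadialProfile:
    """Azimuthally and axially averaged density versus radius.

    Voxels whose z offset from the grid centre lies in ``z_band`` (Å; the
    whole grid when None) are binned by cylindrical radius with bin width
    equal to the voxel size; each bin's value is the plain mean of its
    voxels, i.e. the azimuthal-and-axial average of the density.
    """
    vs = density_map.voxel_size
    nz = density_map.shape[0]
    cz = density_map.centre[0]
    z_offsets = (np.arange(nz) - cz) * vs
    if z_band is None:
        z_sel = np.ones(nz, dtype=bool)
    else:
        z_lo, z_hi = map(float, z_band)
        if not (z_hi > z_lo):
            raise ValueError(f"invalid z_band {z_band}")
        z_sel = (z_offsets >= z_lo) & (z_offsets <= z_hi)
        if not z_sel.any():
            raise ValueError("z_band does not intersect the grid")
    _, y, x = density_map.coordinate_grids()
    r = np.hypot(x, y)[0]
    bin_idx = np.rint(r / vs).astype(int).ravel()
    n_bins = bin_idx.max() + 1
    counts = np.bincount(bin_idx, minlength=n_bins)
    slab = density_map.grid[z_sel]
    sums = np.bincount(bin_idx, weights=slab.sum(axis=0).ravel(), minlength=n_bins)
    occupied = counts > 0  # corner-adjacent bins can be empty on small grids
    mean_density = sums[occupied] / (counts[occupied] * int(z_sel.sum()))
    radii = (np.arange(n_bins) * vs)[occupied]
    return RadialProfile(radii=radii, mean_density=mean_density)


def peak_radius(
    profile: RadialProfile, r_window: tuple[float, float] | None = None
) -> float:
    """Radius (Å) of the profile's maximum, parabolically interpolated.

    ``r_window`` restricts the search to a radial interval.  A flat profile
    has no defined peak and raises ``ValueError``.
    """
    radii, dens = profile.radii, profile.mean_density
    if r_window is not None:
        lo, hi = map(float, r_window)
        sel = (radii >= lo) & (radii <= hi)
        if not sel.any():
            raise ValueError(f"r_window {r_window} contains no profile samples")
        radii, dens = radii[sel], dens[sel]
    span = float(dens.max() - dens.min())
    if span <= 1e-12 * max(abs(float(dens.max())), 1.0):
        raise ValueError("profile is flat; peak radius is undefined")
    i = int(np.argmax(dens))
    if i == 0 or i == len(dens) - 1:
        return float(radii[i])
    # parabola through the three bins around the maximum
    y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(radii[i])
    shift = 0.5 * (y0 - y2) / denom
    step = radii[i] - radii[i - 1]
    return float(radii[i] + shift * step)
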