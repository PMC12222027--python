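"""Fourier shell correlation (FSC) between density maps.

FSC(q) is the normalized cross-correlation of two maps' Fourier transforms
over spherical shells of spatial frequency q.  By convention the resolution
of a reconstruction is 1/q at the first crossing of a threshold: 0.143 for
two independent ("gold-standard") half-maps, 0.5 for a map-versus-model
comparison.  No masking or phase-randomization correction is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import DensityMap

__all__ = [
    "FSCCurve",
    "ResolutionEstimate",
    "HALF_MAP_THRESHOLD",
    "MAP_MODEL_THRESHOLD",
    "fsc_curve",
    "resolution_at_threshold",
]

HALF_MAP_THRESHOLD = 0.143
MAP_MODEL_THRESHOLD = 0.5


@dataclass(frozen=True)
class FSCCurve:
    """Per-shell correlation; ``spatial_frequency`` are shell centres in 1/Å.

    The first shell is DC; for non-empty maps its correlation is 1.
    """

    spatial_frequency: np.ndarray
    correlation: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.spatial_frequency, dtype=float)
        corr = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "spatial_frequency", freq)
        object.__setattr__(self, "correlation", corr)
        if freq.shape != corr.shape or freq.ndim != 1:
            raise ValueError("spatial_frequency and correlation must match 1D shapes")
        if np.any(np.abs(corr) > 1.0 + 1e-9):
            raise ValueError("correlation out of [-1, 1]")


@dataclass(frozen=True)
class ResolutionEstimate:
    """Resolution in Å at a threshold crossing.

    ``crossed`` is False when the curve never falls below the threshold; the
    reported resolution is then the Nyquist bound of the grid.
    """

    resolution_A: float
    threshold: float
    crossed: bool


def fsc_curve(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """FSC between two maps over shells one reciprocal voxel wide.

    Maps must share shape and voxel size.  Symmetric in its arguments, and
    identically 1 when the maps are identical.
    """
    if map_a.shape != map_b.shape:
        raise ValueError(f"shape mismatch: {map_a.shape} vs {map_b.shape}")
    if not np.isclose(map_a.voxel_size, map_b.voxel_size, rtol=1e-6):
        raise ValueError(
            f"voxel size mismatch: {map_a.voxel_size} vs {map_b.voxel_size}"
        )
    vs = map_a.voxel_size
    shape = map_a.shape
    fa = np.fft.fftn(map_a.grid)
    fb = np.fft.fftn(map_b.grid)
    # shell index: radial frequency in units of one reciprocal voxel of the
    # smallest grid dimension
    n_ref = min(shape)
    q_axes = [np.fft.fftfreq(n, d=vs) for n in shape]
    q2 = (
        q_axes[0][:, None, None] ** 2
        + q_axes[1][None, :, None] ** 2
        + q_axes[2][None, None, :] ** 2
    )
    q = np.sqrt(q2)
    shell = np.rint(q * n_ref * vs).astype(int)
    n_shells = n_ref // 2 + 1
    sel = (shell < n_shells).ravel()
    shell_flat = shell.ravel()[sel]
    a_flat = fa.ravel()[sel]
    b_flat = fb.ravel()[sel]
    cross = np.bincount(shell_flat, weights=(a_flat * np.conj(b_flat)).real, minlength=n_shells)
    pa = np.bincount(shell_flat, weights=np.abs(a_flat) ** 2, minlength=n_shells)
    pb = np.bincount(shell_flat, weights=np.abs(b_flat) ** 2, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    freq = np.arange(n_shells) / (n_ref * vs)
    return FSCCurve(spatial_frequency=freq, correlation=corr)


def resolution_at_threshold(curve: FSCCurve, threshold: float) -> ResolutionEstimate:
    """Resolution (Å) at the first crossing below ``threshold``.

    The crossing frequency is linearly interpolated between the last shell
    at or above the threshold and the first below it (DC excluded).  If the
    curve never crosses, the Nyquist resolution is returned with
    ``crossed=False``.
    """
    freq, corr = curve.spatial_frequency, curve.correlation
    below = np.where(corr[1:] < threshold)[0]
    if len(below) == 0:
        return ResolutionEstimate(
            resolution_A=float(1.0 / freq[-1]), threshold=threshold, crossed=False
        )
    i = int(below[0]) + 1  # first shell strictly below the threshold
    f_lo, f_hi = freq[i - 1], freq[i]
    c_lo, c_hi = corr[i - 1], corr[i]
    if c_lo == c_hi or f_lo == 0 and c_lo < threshold:
        f_cross = f_hi
    else:
        f_cross = f_lo + (c_lo - threshold) / (c_lo - c_hi) * (f_hi - f_lo)
    return ResolutionEstimate(
        resolution_A=float(1.0 / f_cross), threshold=threshold, crossed=True
    )
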