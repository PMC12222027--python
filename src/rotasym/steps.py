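"""Bead-assay step detection: from bead orbits to dwell-position counts.

A bead attached to a truncated flagellar filament traces an ellipse (a
tilted circle in projection) as the motor rotates.  When rotation is slowed
— e.g. by partially de-energizing the membrane with the protonophore CCCP —
the rotor pauses at preferred dwell angles, and the number of dwell
positions per revolution reports the periodicity of the rotor–bushing
contact (26 in motors with 26-fold LP-rings).

Pipeline: fit the bead orbit with an algebraic ellipse fit, invert the
ellipse transform to recover the rotor angle for every frame, then count
dwell positions two ways:

* spectrally — the weighted angular power spectrum
  ``S(k) = |Σ_j w_j e^{i k θ_j}|² / (Σ_j w_j)²`` peaks at the number of
  dwells per revolution and is exactly invariant to a global angle offset
  ("phase-invariant dwell positions");
* by density — a wrapped (von Mises) kernel density estimate of the angle
  distribution, whose significant local maxima are the dwell positions.

The spectral estimate is primary; the KDE count is reported alongside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special
from skimage.measure import EllipseModel

from .spectrum import DEFAULT_SIGNIFICANCE_CUT, RotationalSpectrum

__all__ = [
    "BeadTrajectory",
    "OrbitEllipse",
    "AngleSeries",
    "DwellProfile",
    "StepCall",
    "fit_orbit_ellipse",
    "smooth_trajectory",
    "trajectory_to_angles",
    "angular_kde",
    "weighted_angular_power_spectrum",
    "count_dwell_positions",
    "detect_steps",
]

logger = logging.getLogger(__name__)

#: Default harmonic search range; k=1 is excluded because it is dominated by
#: orbit-centring error, not by dwell structure.
DEFAULT_K_RANGE = (2, 60)

#: Default boxcar pre-smoothing window (frames) applied to trajectories by
#: the high-level pipeline.  Dwells in the CCCP-slowed assay span tens of
#: frames, so a short boxcar suppresses localization noise without merging
#: neighbouring dwell angles.
DEFAULT_SMOOTH_WINDOW = 7

_KDE_GRID_SIZE = 1024


@dataclass(frozen=True)
class BeadTrajectory:
    """Timed bead positions: t in seconds (uniformly sampled, strictly
    increasing), x and y in nm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("t", t), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1D arrays of equal length")
        if len(t) == 0:
            raise ValueError("trajectory is empty")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class OrbitEllipse:
    """Bead orbit: centre (nm), semi-axes a >= b > 0 (nm), tilt in radians.

    The orbit point at parametric angle θ is
    ``centre + R(tilt) · (a cos θ, b sin θ)``.
    """

    centre: tuple[float, float]
    a: float
    b: float
    tilt: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")

    def point(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Orbit position(s) at parametric angle(s) θ."""
        theta = np.asarray(theta, dtype=float)
        u = self.a * np.cos(theta)
        v = self.b * np.sin(theta)
        ct, st = np.cos(self.tilt), np.sin(self.tilt)
        return self.centre[0] + ct * u - st * v, self.centre[1] + st * u + ct * v


@dataclass(frozen=True)
class AngleSeries:
    """Rotor angles in [0, 2π) with non-negative weights (frame durations)."""

    theta: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        theta = np.mod(np.asarray(self.theta, dtype=float), 2.0 * np.pi)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "weights", weights)
        if theta.shape != weights.shape or theta.ndim != 1:
            raise ValueError("theta and weights must be 1D arrays of equal length")
        if len(theta) == 0:
            raise ValueError("angle series is empty")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass(frozen=True)
class DwellProfile:
    """Wrapped KDE of the angle distribution on a uniform grid over [0, 2π);
    the trapezoidal integral of ``density`` is 1."""

    angle_grid: np.ndarray
    density: np.ndarray
    kappa: float


@dataclass(frozen=True)
class StepCall:
    """Dwell-position count from the two estimators.

    ``n_steps_spectral`` is None when no harmonic is significant (smooth
    rotation without detectable dwells).  Agreement between the spectral and
    KDE counts is reported, not enforced.
    """

    n_steps_spectral: int | None
    spectral_significance: float
    n_peaks_kde: int
    kde_peak_significances: np.ndarray
    spectrum: RotationalSpectrum
    profile: DwellProfile

    @property
    def estimators_agree(self) -> bool:
        return self.n_steps_spectral is not None and self.n_steps_spectral == self.n_peaks_kde


def fit_orbit_ellipse(traj: BeadTrajectory) -> OrbitEllipse:
    """Least-squares algebraic conic fit of the bead orbit, constrained to
    ellipses.

    Requires at least 6 non-collinear points.  Equivariant under rigid
    motions of the data: translating the trajectory translates the centre,
    rotating it rotates the tilt.
    """
    if len(traj) < 6:
        raise ValueError(f"need >= 6 points to fit an ellipse, got {len(traj)}")
    pts = np.column_stack([traj.x, traj.y])
    # collinearity guard: rank of centred coordinates
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise ValueError("points are collinear; orbit ellipse is degenerate")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed (degenerate input)")
    xc, yc = model.center
    a, b = model.axis_lengths
    tilt = float(model.theta)
    if b > a:
        a, b = b, a
        tilt += np.pi / 2.0
    tilt = float(np.mod(tilt, np.pi))
    return OrbitEllipse(centre=(float(xc), float(yc)), a=float(a), b=float(b), tilt=tilt)


def smooth_trajectory(traj: BeadTrajectory, window: int) -> BeadTrajectory:
    """Centred boxcar average of x and y over ``window`` frames.

    Reduces localization noise by √window at the cost of blurring frames
    that straddle a step transition.  ``window`` is clipped to the trajectory
    length and forced odd so the timestamps stay aligned.
    """
    if window <= 1:
        return traj
    window = min(int(window), len(traj))
    if window % 2 == 0:
        window -= 1
    if window <= 1:
        return traj
    kernel = np.ones(window) / window
    # reflect-pad so the ends keep full support
    pad = window // 2
    x = np.convolve(np.pad(traj.x, pad, mode="reflect"), kernel, mode="valid")
    y = np.convolve(np.pad(traj.y, pad, mode="reflect"), kernel, mode="valid")
    return BeadTrajectory(t=traj.t, x=x, y=y)


def trajectory_to_angles(traj: BeadTrajectory, ellipse: OrbitEllipse) -> AngleSeries:
    """Map bead positions to rotor angles via the inverse ellipse transform.

    Each (x, y) is translated to the orbit centre, rotated by −tilt, scaled
    by (1/a, 1/b) onto the unit circle, and converted with atan2 to an angle
    in [0, 2π).  Frames landing exactly on the centre have no defined angle
    and are dropped (logged).  Weights are per-frame durations, uniform for
    uniformly sampled data.
    """
    dx = traj.x - ellipse.centre[0]
    dy = traj.y - ellipse.centre[1]
    ct, st = np.cos(ellipse.tilt), np.sin(ellipse.tilt)
    u = (ct * dx + st * dy) / ellipse.a
    v = (-st * dx + ct * dy) / ellipse.b
    ok = (u != 0.0) | (v != 0.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d frame(s) at the exact orbit centre", n_dropped)
    if not ok.any():
        raise ValueError("all frames sit at the orbit centre; no angles defined")
    theta = np.mod(np.arctan2(v[ok], u[ok]), 2.0 * np.pi)
    if len(traj) > 1:
        dt = float(np.median(np.diff(traj.t)))
    else:
        dt = 1.0
    weights = np.full(theta.shape, dt)
    return AngleSeries(theta=theta, weights=weights)


def angular_kde(angles: AngleSeries, kappa: float, n_grid: int = _KDE_GRID_SIZE) -> DwellProfile:
    """Weighted wrapped-kernel (von Mises) density of the angle distribution.

    Evaluated by Fourier synthesis: the von Mises kernel of concentration κ
    has circular-harmonic coefficients I_k(κ)/I_0(κ), so the KDE is the
    weighted empirical characteristic function shrunk by those factors —
    exact, O(n·k_cut), and free of grid binning.  Rotating all angles by c
    rotates the profile by exactly c.
    """
    if not (kappa > 0):
        raise ValueError("kappa must be > 0")
    w = angles.weights / angles.weights.sum()
    # harmonic cut where the kernel factor I_k(κ)/I_0(κ) ~ exp(-k²/2κ) < 1e-12
    k_cut = int(np.ceil(np.sqrt(2.0 * kappa * 27.7))) + 2
    k = np.arange(1, k_cut + 1)
    shrink = special.ive(k, kappa) / special.ive(0, kappa)
    keep = shrink > 1e-12
    k, shrink = k[keep], shrink[keep]
    # weighted circular moments
    phases = np.exp(1j * angles.theta)
    moments = np.empty(len(k), dtype=complex)
    z = np.ones_like(phases)
    for i in range(len(k)):
        z = z * phases
        moments[i] = np.sum(w * z)
    grid = 2.0 * np.pi * np.arange(n_grid) / n_grid
    density = np.full(n_grid, 1.0 / (2.0 * np.pi))
    density = density + (
        np.cos(np.outer(grid, k)) @ (shrink * moments.real)
        + np.sin(np.outer(grid, k)) @ (shrink * moments.imag)
    ) / np.pi
    density = np.clip(density, 0.0, None)
    # renormalize the (wrapped) trapezoidal integral to exactly 1
    integral = density.mean() * 2.0 * np.pi
    density = density / integral
    return DwellProfile(angle_grid=grid, density=density, kappa=float(kappa))


def weighted_angular_power_spectrum(angles: AngleSeries, k_max: int) -> RotationalSpectrum:
    """S(k) = |Σ_j w_j e^{ikθ_j}|² / (Σ_j w_j)² for k = 1..k_max.

    S(k) ∈ [0, 1]; S(k) → 1 as the distribution concentrates at points
    spaced 2π/k apart, and S is exactly invariant under a global angle
    offset.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    w = angles.weights / angles.weights.sum()
    phases = np.exp(1j * angles.theta)
    power = np.empty(k_max)
    z = np.ones_like(phases)
    for i in range(k_max):
        z = z * phases
        power[i] = np.abs(np.sum(w * z)) ** 2
    return RotationalSpectrum(np.arange(1, k_max + 1), power)


#: KDE peak cut in units of the analytic null fluctuation (below).
#: Calibrated on 1,000 uniform-null trials (10^4 angles, κ = 4·31²): the
#: largest null peak excursion was 2.1 units; 3 gives zero false positives
#: with a 50% margin.
KDE_PEAK_CUT = 3.0


def _kde_null_sd(kappa: float, n_effective: float) -> float:
    """Sampling sd of a von Mises KDE of uniform angles.

    For weights w_j, Var ρ̂(φ) = (Σw²/(Σw)²)·(I0(2κ)/(2π I0(κ))² − 1/(2π)²);
    the effective sample size is (Σw)²/Σw².  Computed with exponentially
    scaled Bessel functions to stay finite at large κ.
    """
    # I0(2κ)/I0(κ)² = ive(0,2κ)/ive(0,κ)² exactly (the e^{2κ} factors cancel)
    ratio = special.ive(0, 2.0 * kappa) / special.ive(0, kappa) ** 2
    var = (ratio / (2.0 * np.pi) - 1.0 / (4.0 * np.pi**2)) / n_effective
    return float(np.sqrt(max(var, 0.0)))


def _kde_peaks(
    profile: DwellProfile, n_effective: float, peak_cut: float = KDE_PEAK_CUT
) -> tuple[int, np.ndarray]:
    """Count wrapped local maxima significantly above the uniform level.

    A peak is significant when its excess over the uniform density 1/2π
    exceeds ``peak_cut`` analytic null standard deviations.  (A robust-MAD
    cut on the profile itself is unusable here: the dwell bumps of a true
    signal inflate the profile's own MAD and mask the peaks.)
    """
    d = profile.density
    sd = _kde_null_sd(profile.kappa, n_effective)
    if sd == 0.0:
        return 0, np.zeros(0)
    sig = (d - 1.0 / (2.0 * np.pi)) / sd
    is_max = (d > np.roll(d, 1)) & (d >= np.roll(d, -1))
    peaks = is_max & (sig >= peak_cut)
    return int(peaks.sum()), sig[peaks]


def count_dwell_positions(
    angles: AngleSeries,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    kappa: float | None = None,
    significance_cut: float = DEFAULT_SIGNIFICANCE_CUT,
) -> StepCall:
    """Count dwell positions per revolution, spectrally and by KDE.

    The spectral count is the significant argmax of the weighted angular
    power spectrum over ``k_range`` (None if nothing is significant).  The
    KDE bandwidth defaults to κ = 4k² at the spectral count k (kernel sd of
    roughly a twelfth of a dwell spacing), so the profile resolves
    neighbouring dwells without fragmenting them.
    """
    k_min, k_max = k_range
    if k_min < 2 or k_max < k_min:
        raise ValueError(f"invalid k_range {k_range}")
    spectrum = weighted_angular_power_spectrum(angles, k_max)
    searched = spectrum.restricted(k_min, k_max)
    found = searched.significant_peak(significance_cut)
    if found is None:
        _, _, significance = searched.most_significant()
        n_spectral: int | None = None
    else:
        k_star, _, significance = found
        n_spectral = int(k_star)
    k_for_kappa = n_spectral if n_spectral is not None else (k_min + k_max) // 2
    if kappa is None:
        kappa = 4.0 * float(k_for_kappa) ** 2
    profile = angular_kde(angles, kappa)
    n_effective = float(angles.weights.sum() ** 2 / np.sum(angles.weights**2))
    n_kde, kde_sig = _kde_peaks(profile, n_effective)
    return StepCall(
        n_steps_spectral=n_spectral,
        spectral_significance=float(significance),
        n_peaks_kde=n_kde,
        kde_peak_significances=kde_sig,
        spectrum=spectrum,
        profile=profile,
    )


def detect_steps(
    traj: BeadTrajectory,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    kappa: float | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    significance_cut: float = DEFAULT_SIGNIFICANCE_CUT,
) -> StepCall:
    """Full pipeline: smooth → fit orbit → angles → dwell-position count."""
    smoothed = smooth_trajectory(traj, smooth_window)
    ellipse = fit_orbit_ellipse(smoothed)
    angles = trajectory_to_angles(smoothed, ellipse)
    return count_dwell_positions(
        angles, k_range=k_range, kappa=kappa, significance_cut=significance_cut
    )
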