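"""Power versus integer harmonic, shared by map-symmetry and step detection.

A :class:`RotationalSpectrum` holds the power ``S(k)`` of a periodic signal
at integer harmonics ``k`` — the azimuthal density of a ring structure, or
the angular dwell distribution of a stepping rotor.  Peak significance is
measured in robust units: median absolute deviations (MADs) of the spectrum
above its median, so a single dominant harmonic does not inflate its own
noise estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RotationalSpectrum", "DEFAULT_SIGNIFICANCE_CUT"]

# Peak-significance cut in local-MAD units, shared by map-symmetry calls and
# dwell-step calls.  Calibrated to zero false positives on null trials of
# each detector: 3,000 uniform-angle spectra, 600 smoothly-rotating-bead
# pipelines and 1,500 pure-noise maps never exceeded 69; true phantom and
# dwell signals score from ~70 (hardest stepping case) to >10^9 (noiseless
# maps).  See docs/methods.md.
DEFAULT_SIGNIFICANCE_CUT = 70.0


@dataclass(frozen=True)
class RotationalSpectrum:
    """Power S(k) at strictly increasing integer harmonics k >= 1."""

    harmonics: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        harmonics = np.asarray(self.harmonics, dtype=int)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "harmonics", harmonics)
        object.__setattr__(self, "power", power)
        if harmonics.shape != power.shape or harmonics.ndim != 1:
            raise ValueError("harmonics and power must be 1D arrays of equal length")
        if len(harmonics) == 0:
            raise ValueError("spectrum is empty")
        if harmonics[0] < 1 or np.any(np.diff(harmonics) <= 0):
            raise ValueError("harmonics must be strictly increasing and >= 1")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")

    def significance(self, half_window: int = 10, exclude: int = 2) -> np.ndarray:
        """Per-harmonic significance against a local running background.

        The reported significance of each harmonic is the larger of two
        robust z-scores:

        * against a local background — median and MAD of the power over
          harmonics within ``half_window`` of k, excluding k itself and its
          ``exclude`` nearest neighbours on each side (a sharp peak must not
          inflate its own background, and real peaks carry close sidebands
          when the underlying angle estimate has a residual low-order
          distortion).  The local background matters because spectra of
          finite trajectories are coloured: correlated sampling piles power
          into low harmonics, which a global normalizer mistakes for signal
          while under-rating genuine high-k peaks.
        * against the global background — median and MAD over the whole
          spectrum.  This rescues low fundamentals whose overtone comb
          (k, 2k, 3k, ...) fills the local window and would otherwise mask
          the fundamental.

        The false-positive rate of the combined score is what the packaged
        significance cut is calibrated against.
        """
        n = len(self.power)
        med_g = float(np.median(self.power))
        mad_g = max(float(np.median(np.abs(self.power - med_g))), 0.3 * med_g)
        if mad_g > 0:
            sig_global = (self.power - med_g) / mad_g
        else:
            sig_global = np.zeros(n)
        sig = np.zeros(n)
        for i in range(n):
            dk = np.abs(self.harmonics - self.harmonics[i])
            window = (dk <= half_window) & (dk > exclude)
            if window.sum() < 4:  # tiny spectrum: fall back to everything else
                window = dk > exclude
            if not window.any():
                continue
            local = self.power[window]
            med = float(np.median(local))
            # floor the MAD at a fraction of the local level: a window that
            # happens to be unusually tight must not manufacture significance
            mad = max(float(np.median(np.abs(local - med))), 0.3 * med)
            if mad == 0.0:
                continue
            sig[i] = (self.power[i] - med) / mad
        return np.maximum(sig, sig_global)

    def peak(self) -> tuple[int, float, float]:
        """(harmonic, power, significance) of the highest-power harmonic."""
        sig = self.significance()
        i = int(np.argmax(self.power))
        return int(self.harmonics[i]), float(self.power[i]), float(sig[i])

    def most_significant(self) -> tuple[int, float, float]:
        """(harmonic, power, significance) of the most significant harmonic.

        The power baseline of a finite-trajectory spectrum is coloured, so
        the strongest harmonic in absolute power can sit on the low-k
        continuum while the real periodicity stands far above its local
        background.
        """
        sig = self.significance()
        i = int(np.argmax(sig))
        return int(self.harmonics[i]), float(self.power[i]), float(sig[i])

    def significant_peak(self, cut: float) -> tuple[int, float, float] | None:
        """Strongest-power harmonic among those with significance >= cut.

        Detectors use this two-stage rule: significance decides *whether*
        a periodicity is present (so the coloured low-k continuum cannot
        win), and power decides *which* of the significant harmonics is the
        periodicity (so a close sideband of the true peak cannot outrank it
        on a background fluctuation).  Returns None when nothing passes.
        """
        sig = self.significance()
        passing = sig >= cut
        if not passing.any():
            return None
        idx = np.flatnonzero(passing)
        i = int(idx[np.argmax(self.power[idx])])
        return int(self.harmonics[i]), float(self.power[i]), float(sig[i])

    def restricted(self, k_min: int, k_max: int) -> "RotationalSpectrum":
        sel = (self.harmonics >= k_min) & (self.harmonics <= k_max)
        if not sel.any():
            raise ValueError(f"no harmonics in [{k_min}, {k_max}]")
        return RotationalSpectrum(self.harmonics[sel], self.power[sel])
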