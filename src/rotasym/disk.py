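"""Concentric-ring stoichiometry of the flagellar basal disk.

The basal disk of *Campylobacter jejuni* is a stack of concentric FlgP rings.
The innermost ring holds 51 protomers (17 trimeric repeats, matching the
motor's 17-fold periplasmic scaffold).  Under the constant-arc-spacing model,
every ring packs protomers at the same arc length ``s = 2*pi*R1/n1`` as the
innermost ring, so ring *i* at radius ``R_i`` carries
``n_i = round(n1 * R_i / R1)`` protomers.  With the packaged ring-spacing
ratio this adds 11 protomers per ring, which is why outer rings cannot share
the 17-fold symmetry of the rest of the periplasmic scaffold.

The cogwheel utilities quantify symmetry mismatches between rotor and stator
components (e.g. 17 stator complexes against a 38-tooth C-ring): when the
counts are coprime every stator meets the rotor teeth at a different phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiskLatticeModel",
    "CogPair",
    "arc_spacing",
    "ring_radii",
    "ring_protomer_counts",
    "protomer_increment",
    "asu_total",
    "symmetry_mismatch",
    "mesh_registry",
]

#: Ring-spacing-to-inner-radius ratio shipped as the package default.
#: Derived so that round(n1 * (1 + ratio)) - n1 reproduces the observed
#: +11 protomers per ring for an inner ring of 51; overridable per model.
DEFAULT_SPACING_RATIO = 0.216


@dataclass(frozen=True)
class DiskLatticeModel:
    """Concentric-ring lattice: inner radius R1 (Å), inner count n1,
    radial spacing Δr expressed as ``spacing_ratio = Δr / R1``."""

    R1: float
    n1: int
    spacing_ratio: float = DEFAULT_SPACING_RATIO
    n_rings: int = 1

    def __post_init__(self) -> None:
        if not (self.R1 > 0):
            raise ValueError("R1 must be > 0")
        if self.n1 < 1:
            raise ValueError("n1 must be >= 1")
        if not (self.spacing_ratio > 0):
            raise ValueError("spacing_ratio must be > 0")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")


@dataclass(frozen=True)
class CogPair:
    """``n_small`` small cogs (stator complexes) evenly spaced around a big
    cog with ``m_teeth`` teeth (C-ring periodicity)."""

    n_small: int
    m_teeth: int

    def __post_init__(self) -> None:
        if self.n_small < 1 or self.m_teeth < 1:
            raise ValueError("cog counts must be >= 1")


def arc_spacing(R1: float, n1: int) -> float:
    """Arc length between adjacent protomers on a ring: 2πR1/n1 (Å)."""
    if not (R1 > 0):
        raise ValueError("R1 must be > 0")
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    return 2.0 * math.pi * R1 / n1


def ring_radii(model: DiskLatticeModel) -> np.ndarray:
    """Radius of each ring: R_i = R1·(1 + spacing_ratio·(i−1)), i = 1..n_rings."""
    i = np.arange(model.n_rings)
    return model.R1 * (1.0 + model.spacing_ratio * i)


def ring_protomer_counts(model: DiskLatticeModel) -> list[int]:
    """Protomer count per ring under constant arc spacing.

    n_i = round(n1 · R_i / R1), rounded half-to-even (the model fixes only
    the ratio of circumferences, so exact halves have no preferred side).
    """
    ratios = ring_radii(model) / model.R1
    return [int(x) for x in np.rint(model.n1 * ratios)]


def protomer_increment(model: DiskLatticeModel) -> int:
    """Common per-ring protomer increment; raises if the increments differ.

    For models where rounding makes the increment non-constant there is no
    single answer and callers should inspect ``ring_protomer_counts``.
    """
    counts = ring_protomer_counts(model)
    if len(counts) < 2:
        raise ValueError("need at least 2 rings to define an increment")
    increments = np.diff(counts)
    if not np.all(increments == increments[0]):
        raise ValueError(f"protomer increment is not constant: {increments.tolist()}")
    return int(increments[0])


def asu_total(symmetry_order: int, protomers_per_asu: int) -> int:
    """Total protomer count: symmetry order × protomers per asymmetric unit."""
    if symmetry_order < 1 or protomers_per_asu < 1:
        raise ValueError("symmetry_order and protomers_per_asu must be >= 1")
    return symmetry_order * protomers_per_asu


def symmetry_mismatch(a: int, b: int) -> tuple[int, int]:
    """(gcd, coincidence period) of two cyclic symmetry orders.

    gcd = 1 means a full mismatch: no rotation short of the full coincidence
    period ``lcm(a, b)`` superimposes both symmetries.
    """
    if a < 1 or b < 1:
        raise ValueError("symmetry orders must be >= 1")
    g = math.gcd(a, b)
    return g, a * b // g


def mesh_registry(pair: CogPair) -> tuple[np.ndarray, int]:
    """Tooth-engagement phase of each small cog around the big cog.

    Small cog ``k`` sits at azimuth ``2πk/n_small`` and meets the big cog's
    tooth pattern at phase ``frac(m_teeth · k / n_small)`` (in tooth units,
    [0, 1)).  The number of distinct phases is ``n_small / gcd(n_small,
    m_teeth)``: coprime counts force every small cog into a different
    rotational register.
    """
    k = np.arange(pair.n_small)
    phases = np.mod(pair.m_teeth * k / pair.n_small, 1.0)
    n_distinct = pair.n_small // math.gcd(pair.n_small, pair.m_teeth)
    return phases, n_distinct
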