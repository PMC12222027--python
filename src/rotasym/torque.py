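"""Additive stator torque model for flagellar motors.

Each stator complex exerts a tangential force ``F`` (pN) on the C-ring at a
contact radius ``r`` (nm) from the rotation axis.  Treating the stator
contributions as additive, a ring of ``N`` engaged stator complexes delivers
a maximum torque

    τ = N · F · r   (pN·nm).

The model is deliberately minimal — no load line, duty-ratio or occupancy
dynamics — and exists to connect structure-derived stator counts and radii
to measured torques.  Units are enforced: forces in pN, radii in nm, torque
in pN·nm; map-derived radii in Å must be converted explicitly
(:func:`angstrom_to_nm`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StatorRing",
    "TorquePrediction",
    "predict_torque",
    "infer_stator_force",
    "compare_motors",
    "angstrom_to_nm",
    "nm_to_angstrom",
    "CJEJUNI_STATOR_RING",
    "ECOLI_STATOR_RING",
]


def angstrom_to_nm(value_angstrom: float) -> float:
    """Explicit Å → nm conversion (1 nm = 10 Å)."""
    return value_angstrom / 10.0


def nm_to_angstrom(value_nm: float) -> float:
    """Explicit nm → Å conversion."""
    return value_nm * 10.0


@dataclass(frozen=True)
class StatorRing:
    """A ring of stator complexes around the C-ring.

    Attributes
    ----------
    n_stators:
        Number of engaged stator complexes (N ≥ 0).
    force_pN:
        Tangential force per stator complex, pN.
    radius_nm:
        Stator–C-ring contact radius, nm.  Values above 100 are rejected as a
        guard against passing Å by mistake (no known motor approaches a
        100 nm contact radius).
    """

    n_stators: int
    force_pN: float
    radius_nm: float

    def __post_init__(self) -> None:
        if self.n_stators < 0:
            raise ValueError("n_stators must be >= 0")
        if self.force_pN < 0:
            raise ValueError("force_pN must be >= 0")
        if self.radius_nm < 0:
            raise ValueError("radius_nm must be >= 0")
        if self.radius_nm > 100.0:
            raise ValueError(
                f"radius_nm = {self.radius_nm:g} nm is implausibly large; "
                "map radii in Å must be converted with angstrom_to_nm()"
            )


@dataclass(frozen=True)
class TorquePrediction:
    torque_pN_nm: float
    ring: StatorRing


# Packaged motor constants.  Stator counts and the 7.3 pN per-stator force
# are literature values; the contact radii are structural constants derived
# from the corresponding torque predictions (they are not independently
# tabulated) and can be overridden by users who measure radii from maps.
CJEJUNI_STATOR_RING = StatorRing(n_stators=17, force_pN=7.3, radius_nm=26.5)
ECOLI_STATOR_RING = StatorRing(n_stators=11, force_pN=7.3, radius_nm=20.0)


def predict_torque(ring: StatorRing) -> TorquePrediction:
    """Maximum torque of the additive model: τ = N·F·r, in pN·nm."""
    return TorquePrediction(
        torque_pN_nm=ring.n_stators * ring.force_pN * ring.radius_nm,
        ring=ring,
    )


def infer_stator_force(torque_pN_nm: float, n_stators: int, radius_nm: float) -> float:
    """Per-stator force (pN) implied by a torque: F = τ/(N·r).

    Exact inverse of :func:`predict_torque`.
    """
    if n_stators <= 0:
        raise ValueError("n_stators must be > 0 to invert for force")
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0 to invert for force")
    return torque_pN_nm / (n_stators * radius_nm)


def compare_motors(ring_a: StatorRing, ring_b: StatorRing) -> dict:
    """Torque ratio of two motors, decomposed into N-, F- and r-ratios.

    The additive model is multiplicative in its three inputs, so
    ``torque_ratio == n_ratio * force_ratio * radius_ratio`` exactly.
    """
    torque_a = predict_torque(ring_a).torque_pN_nm
    torque_b = predict_torque(ring_b).torque_pN_nm
    if torque_b == 0:
        raise ZeroDivisionError("reference motor has zero torque")
    if ring_b.n_stators == 0 or ring_b.force_pN == 0 or ring_b.radius_nm == 0:
        raise ZeroDivisionError("reference motor has a zero factor")
    return {
        "torque_a_pN_nm": torque_a,
        "torque_b_pN_nm": torque_b,
        "torque_ratio": torque_a / torque_b,
        "n_ratio": ring_a.n_stators / ring_b.n_stators,
        "force_ratio": ring_a.force_pN / ring_b.force_pN,
        "radius_ratio": ring_a.radius_nm / ring_b.radius_nm,
    }
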