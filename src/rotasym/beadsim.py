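"""Stochastic simulation of a stepping rotor observed through a bead.

Emulates the slowed bead assay: a rotor with ``n_steps_per_rev`` equally
spaced dwell angles jumps between neighbouring dwells after exponentially
distributed waits (occasionally backwards), and a bead on an elliptical
orbit reports the rotor angle through noisy (x, y) localizations sampled at
a fixed frame rate.  Steps are instantaneous and the bead relaxes to the new
dwell point immediately — the assay's relaxation time is far below one frame
at the slowed rotation rates simulated here.

Every simulation is a pure function of its parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .steps import BeadTrajectory, OrbitEllipse

__all__ = ["StepSimParams", "simulate_stepping_trajectory", "simulate_dwell_angles"]


def _default_orbit() -> OrbitEllipse:
    # a 1.3-µm bead on a truncated filament traces a projected orbit of a
    # few hundred nm; an aspect ratio well off unity exercises the ellipse
    # inversion rather than hiding it
    return OrbitEllipse(centre=(0.0, 0.0), a=150.0, b=90.0, tilt=0.4)


@dataclass(frozen=True)
class StepSimParams:
    """Parameters of the stepping-bead simulation.

    Defaults describe a CCCP-slowed motor watched by a high-speed camera:
    26 dwell angles per revolution, 1,000 frames/s, and a stepping rate of
    50 s⁻¹ so a mean dwell spans 20 frames; localization noise of 20 nm per
    coordinate on a 150 × 90 nm orbit.  ``back_step_prob`` is the chance a
    step goes backwards (0 by default: the assay strain cannot switch).
    """

    seed: int
    n_steps_per_rev: int = 26
    step_rate: float = 50.0
    frames: int = 100_000
    fps: float = 1000.0
    orbit: OrbitEllipse = field(default_factory=_default_orbit)
    noise_sd: float = 20.0
    back_step_prob: float = 0.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps_per_rev < 2:
            raise ValueError("n_steps_per_rev must be >= 2")
        if self.step_rate < 0:
            raise ValueError("step_rate must be >= 0")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if not (self.fps > 0):
            raise ValueError("fps must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.back_step_prob < 1.0):
            raise ValueError("back_step_prob must be in [0, 1)")


def simulate_dwell_angles(params: StepSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth rotor angle at each frame time.

    Returns ``(t, theta)`` where ``theta[i]`` is the dwell angle occupied at
    frame time ``t[i] = i / fps``.  Useful for round-trip tests of the angle
    extraction; :func:`simulate_stepping_trajectory` builds on it.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.frames) / params.fps
    total_time = params.frames / params.fps
    if params.step_rate == 0:
        dwell_index = np.zeros(params.frames, dtype=np.int64)
    else:
        # draw enough exponential waits to cover the observation window
        expected = params.step_rate * total_time
        n_events = max(16, int(expected + 6.0 * np.sqrt(expected) + 16))
        waits = rng.exponential(1.0 / params.step_rate, size=n_events)
        while waits.sum() < total_time:
            waits = np.concatenate(
                [waits, rng.exponential(1.0 / params.step_rate, size=n_events)]
            )
        event_times = np.cumsum(waits)
        directions = np.where(
            rng.random(len(waits)) < params.back_step_prob, -1, 1
        ).astype(np.int64)
        cumulative = np.concatenate([[0], np.cumsum(directions)])
        dwell_index = cumulative[np.searchsorted(event_times, t, side="right")]
    theta = params.phase0 + 2.0 * np.pi * dwell_index / params.n_steps_per_rev
    return t, np.mod(theta, 2.0 * np.pi)


def simulate_stepping_trajectory(params: StepSimParams) -> BeadTrajectory:
    """Simulated bead trajectory: orbit point at the dwell angle plus noise.

    With ``step_rate=0`` and ``noise_sd=0`` every sample coincides with the
    dwell point at ``phase0``; over long runs the occupancy of the dwell
    angles is uniform.  Identical parameters (including seed) give
    bit-identical trajectories.
    """
    t, theta = simulate_dwell_angles(params)
    x, y = params.orbit.point(theta)
    if params.noise_sd > 0:
        # separate stream so the noise does not depend on how many stepping
        # draws were consumed above
        noise_rng = np.random.default_rng((params.seed, 1))
        x = x + noise_rng.normal(0.0, params.noise_sd, size=params.frames)
        y = y + noise_rng.normal(0.0, params.noise_sd, size=params.frames)
    return BeadTrajectory(t=t, x=x, y=y)
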