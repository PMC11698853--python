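"""Fully trained hitchhiker dynamics: discrete decisions vs. potential pull.

Two transport models share one decision diagram.  The Q-variant re-enacts
the training dynamics greedily (attach to the nearest in-range particle iff
its orientation falls in the GO set, re-decide every perception time); the
potential variant is continuously attracted to *all* in-range particles
with GO orientations through a non-reciprocal soft potential and has no
perception time.  Neither model acts back on the bath.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .bath import BathState, init_bath, minimum_image
from .diagram import DecisionDiagram
from .params import BathParams, PotentialParams


@dataclass
class IHPTrajectory:
    """Unwrapped hitchhiker path sampled every integration step.

    ``epoch_attached`` / ``epoch_partners`` log the per-decision outcome of
    the Q-variant; they are empty for the potential variant, whose
    "decisions" are implicit in the continuous force.
    """

    times: np.ndarray
    positions: np.ndarray
    perception_time: float = 1.0
    epoch_attached: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    epoch_partners: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must increase with uniform spacing")


def _bath_arrays(state: BathState):
    n = state.n_particles
    x = np.ascontiguousarray(state.positions[:, 0], dtype=float) if n else np.empty(0)
    y = np.ascontiguousarray(state.positions[:, 1], dtype=float) if n else np.empty(0)
    phi = np.ascontiguousarray(state.angles, dtype=float)
    return x, y, phi


def simulate_q_ihp(
    diagram: DecisionDiagram,
    bath_params: BathParams,
    duration: float,
    rng: np.random.Generator,
    perception_time: float = 1.0,
    scan_radius: float = 1.0,
    bath_state: BathState | None = None,
    noise_scale: np.ndarray | None = None,
) -> IHPTrajectory:
    """Greedy decision-driven hitchhiker for a fixed time horizon.

    Identical dynamics to a training episode with ``epsilon = 0`` and the
    greedy rule read from ``diagram.go_mask``, but without learning and
    without terminating at the box edges (the box only wraps the bath).
    """
    m = int(round(perception_time / bath_params.dt))
    if abs(m * bath_params.dt - perception_time) > 1e-9 or m < 1:
        raise ValueError("perception_time must be an integer multiple of dt")
    n_epochs = int(round(duration / perception_time))
    if n_epochs < 1:
        raise ValueError("duration must cover at least one decision epoch")
    state = bath_state.copy() if bath_state is not None else init_bath(bath_params, rng)
    x, y, phi = _bath_arrays(state)
    if noise_scale is None:
        sigma = np.full(state.n_particles, bath_params.noise_amplitude)
    else:
        sigma = np.broadcast_to(np.asarray(noise_scale, float), (state.n_particles,)).copy()
    n_steps = n_epochs * m
    traj_x = np.empty(n_steps + 1)
    traj_y = np.empty(n_steps + 1)
    attached = np.empty(n_epochs, np.bool_)
    partners = np.empty(n_epochs, np.int64)
    kernels.simulate_q_kernel(
        diagram.go_mask,
        x,
        y,
        phi,
        sigma,
        bath_params.circ_frequency,
        bath_params.speed,
        bath_params.dt,
        bath_params.box_length,
        scan_radius,
        m,
        n_epochs,
        int(rng.integers(0, 2**31 - 1)),
        traj_x,
        traj_y,
        attached,
        partners,
    )
    times = np.arange(n_steps + 1) * bath_params.dt
    return IHPTrajectory(times, np.column_stack((traj_x, traj_y)), perception_time, attached, partners)


def potential_pair_velocity(
    displacement: np.ndarray,
    phi: float,
    pp: PotentialParams,
    diagram: DecisionDiagram,
) -> np.ndarray:
    """Mobility-normalised pull of one bath particle on the hitchhiker.

    ``displacement`` points from the hitchhiker to the particle.  The pull
    has magnitude ``force_scale * v0 * R_s^2 / r^2`` toward the particle
    for ``r_min <= r <= R_s`` and a GO orientation, and vanishes otherwise
    (in particular inside the lower cut-off, where the potential is flat:
    an already-attached hitchhiker needs no further kick).
    """
    d = np.asarray(displacement, dtype=float)
    r = float(np.hypot(d[0], d[1]))
    if r < pp.r_min or r > pp.scan_radius or not diagram.contains(phi):
        return np.zeros(2)
    mag = pp.force_scale * pp.speed * pp.scan_radius**2 / r**2
    return mag * d / r


def step_potential_ihp(
    ihp_pos: np.ndarray,
    bath_state: BathState,
    pp: PotentialParams,
    diagram: DecisionDiagram,
    dt: float,
    box_length: float,
) -> np.ndarray:
    """One overdamped step of the potential hitchhiker against a frozen bath.

    The displacement is ``dt`` times the summed pair pulls (minimum-image
    geometry); if it exceeds the distance to the nearest contributing
    particle it is rescaled to exactly that distance, so a finite time step
    can never overshoot past the closest attractor.
    """
    pos = np.asarray(ihp_pos, dtype=float)
    if bath_state.n_particles == 0:
        return pos.copy()
    wrapped = pos % box_length
    delta = minimum_image(bath_state.positions - wrapped, box_length)
    r = np.hypot(delta[:, 0], delta[:, 1])
    go = np.fromiter(
        (diagram.contains(a) for a in bath_state.angles), bool, bath_state.n_particles
    )
    contributing = go & (r >= pp.r_min) & (r <= pp.scan_radius)
    if not contributing.any():
        return pos.copy()
    rc = r[contributing]
    mags = pp.force_scale * pp.speed * pp.scan_radius**2 / rc**2
    vel = (mags / rc) @ delta[contributing]
    disp = vel * dt
    step_len = float(np.hypot(disp[0], disp[1]))
    nearest = float(rc.min())
    if step_len > nearest:
        disp *= nearest / step_len
    return pos + disp


def simulate_potential_ihp(
    diagram: DecisionDiagram,
    bath_params: BathParams,
    duration: float,
    rng: np.random.Generator,
    pp: PotentialParams | None = None,
    bath_state: BathState | None = None,
    noise_scale: np.ndarray | None = None,
) -> IHPTrajectory:
    """Potential hitchhiker over a fixed horizon; the bath advances first at
    every step and the hitchhiker then responds to the post-step bath."""
    if pp is None:
        pp = PotentialParams(speed=bath_params.speed)
    n_steps = int(round(duration / bath_params.dt))
    if n_steps < 1:
        raise ValueError("duration must cover at least one step")
    state = bath_state.copy() if bath_state is not None else init_bath(bath_params, rng)
    x, y, phi = _bath_arrays(state)
    if noise_scale is None:
        sigma = np.full(state.n_particles, bath_params.noise_amplitude)
    else:
        sigma = np.broadcast_to(np.asarray(noise_scale, float), (state.n_particles,)).copy()
    traj_x = np.empty(n_steps + 1)
    traj_y = np.empty(n_steps + 1)
    kernels.simulate_potential_kernel(
        diagram.go_mask,
        x,
        y,
        phi,
        sigma,
        bath_params.circ_frequency,
        bath_params.speed,
        bath_params.dt,
        bath_params.box_length,
        pp.scan_radius,
        pp.r_min,
        pp.force_scale,
        n_steps,
        int(rng.integers(0, 2**31 - 1)),
        traj_x,
        traj_y,
    )
    times = np.arange(n_steps + 1) * bath_params.dt
    return IHPTrajectory(times, np.column_stack((traj_x, traj_y)))
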