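"""Periodic 2D bath of non-interacting (chiral) active Brownian particles.

Equations of motion (forward Euler--Maruyama with step ``dt``):

    r_i(t + dt)   = r_i(t) + v0 * dt * (cos phi_i(t), sin phi_i(t))
    phi_i(t + dt) = phi_i(t) + omega * dt + sqrt(2 * D_r * dt) * eta

with independent standard-normal ``eta``.  The translation always uses the
pre-step orientation; the orientational noise is drawn afterwards.
Positions live in the half-open box ``[0, L)^2`` with periodic boundaries,
orientations are stored wrapped to ``[0, 2*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import TWO_PI, BathParams


@dataclass
class BathState:
    """Positions (N, 2), orientations (N,) and elapsed time of the bath."""

    positions: np.ndarray
    angles: np.ndarray
    time: float = 0.0

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "BathState":
        return BathState(self.positions.copy(), self.angles.copy(), self.time)


def init_bath(params: BathParams, rng: np.random.Generator) -> BathState:
    """Draw a homogeneous bath: positions uniform over the box, orientations
    uniform over the circle."""
    n = params.n_particles
    positions = rng.uniform(0.0, params.box_length, size=(n, 2))
    angles = rng.uniform(0.0, TWO_PI, size=n)
    return BathState(positions, angles, 0.0)


def step_bath(
    state: BathState,
    params: BathParams,
    rng: np.random.Generator,
    noise_scale: float | np.ndarray | None = None,
) -> BathState:
    """Advance every particle by one Euler--Maruyama step of length ``dt``.

    ``noise_scale`` overrides the per-particle orientational kick amplitude
    ``sqrt(2 D_r dt)``; scripted test fixtures pass zeros for noiseless
    particles.  A fresh state is returned; the input is left untouched.
    """
    if noise_scale is None:
        noise_scale = params.noise_amplitude
    disp = params.speed * params.dt
    positions = state.positions + disp * np.column_stack(
        (np.cos(state.angles), np.sin(state.angles))
    )
    positions %= params.box_length
    eta = rng.standard_normal(state.n_particles)
    angles = (state.angles + params.circ_frequency * params.dt + noise_scale * eta) % TWO_PI
    return BathState(positions, angles, state.time + params.dt)


def abp_msd_closed_form(t: np.ndarray, params: BathParams) -> np.ndarray:
    """Mean-squared displacement of a free achiral active Brownian particle,

        MSD(t) = (2 v0^2 / D_r^2) * (D_r t + exp(-D_r t) - 1),

    ballistic ``v0^2 t^2`` at short times and diffusive ``2 v0^2 t / D_r``
    for ``t >> 1/D_r``.  Only defined for ``D_r > 0`` and ``omega = 0``.
    """
    if params.rot_diffusivity <= 0:
        raise ValueError("closed form requires rot_diffusivity > 0")
    if params.circ_frequency != 0:
        raise ValueError("closed form only covers achiral particles (omega = 0)")
    t = np.asarray(t, dtype=float)
    dr = params.rot_diffusivity
    # expm1 keeps the short-time limit v0^2 t^2 accurate despite cancellation
    return 2.0 * params.speed**2 / dr**2 * (dr * t + np.expm1(-dr * t))


def minimum_image(delta: np.ndarray, box_length: float) -> np.ndarray:
    """Map coordinate differences to the nearest periodic image."""
    return delta - box_length * np.round(delta / box_length)


def nearest_particle(
    point: np.ndarray,
    state: BathState,
    scan_radius: float,
    box_length: float,
) -> int | None:
    """Index of the closest particle by minimum-image distance, or ``None``
    if the bath is empty or the closest particle lies beyond ``scan_radius``."""
    if state.n_particles == 0:
        return None
    delta = minimum_image(state.positions - np.asarray(point, dtype=float), box_length)
    d2 = np.einsum("ij,ij->i", delta, delta)
    j = int(np.argmin(d2))
    if d2[j] > scan_radius**2:
        return None
    return j


def simulate_free_abp(
    params: BathParams,
    n_particles: int,
    times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unwrapped positions of ``n_particles`` independent free particles,
    all starting at the origin with uniform random orientations, sampled at
    ``times`` (each an integer multiple of ``dt``).

    Returns an array of shape ``(len(times), n_particles, 2)``; used as the
    Monte-Carlo counterpart of :func:`abp_msd_closed_form`.
    """
    times = np.asarray(times, dtype=float)
    steps = np.round(times / params.dt).astype(int)
    if not np.allclose(steps * params.dt, times, atol=1e-9):
        raise ValueError("sample times must be integer multiples of dt")
    n_steps = int(steps.max(initial=0))
    pos = np.zeros((n_particles, 2))
    phi = rng.uniform(0.0, TWO_PI, size=n_particles)
    out = np.empty((len(times), n_particles, 2))
    want = {s: i for i, s in enumerate(steps)}
    if 0 in want:
        out[want[0]] = pos
    disp = params.speed * params.dt
    drift = params.circ_frequency * params.dt
    sigma = params.noise_amplitude
    for k in range(1, n_steps + 1):
        pos[:, 0] += disp * np.cos(phi)
        pos[:, 1] += disp * np.sin(phi)
        phi += drift + sigma * rng.standard_normal(n_particles)
        if k in want:
            out[want[k]] = pos
    return out
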