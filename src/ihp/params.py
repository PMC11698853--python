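"""Parameter containers and unit conventions.

All lengths are measured in units of the hitchhiker's scan radius ``R_s``
(the farthest distance at which a bath particle can be perceived) and all
times in units of the perception time ``tau_Q`` (the interval between two
successive decisions of the learning hitchhiker).  The navigational goal
lies along the positive-x axis of the simulation frame, i.e. along polar
angle 0, half a box length away from the agent's starting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

TWO_PI = 2.0 * math.pi

#: rotational diffusivity used for most of the worked examples (per tau_Q)
DEFAULT_ROT_DIFFUSIVITY = 6.0 * math.pi**2 * 1.0e-3


@dataclass(frozen=True)
class BathParams:
    """Physical parameters of the periodic 2D bath of active particles.

    The bath consists of ``n_particles = round(density * box_length**2)``
    non-interacting (chiral) active Brownian particles moving at constant
    speed along their orientation, which undergoes rotational diffusion with
    diffusivity ``rot_diffusivity`` and, for chiral particles, drifts at the
    constant circular frequency ``circ_frequency``.  Translational diffusion
    is neglected.
    """

    box_length: float = 25.0
    density: float = 0.6
    speed: float = 1.5
    rot_diffusivity: float = DEFAULT_ROT_DIFFUSIVITY
    circ_frequency: float = 0.0
    dt: float = 1.0 / 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.rot_diffusivity < 0:
            raise ValueError("rot_diffusivity must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def from_count(cls, n_particles: int, box_length: float = 25.0, **kw) -> "BathParams":
        """Build parameters for exactly ``n_particles`` in a given box."""
        if n_particles < 0:
            raise ValueError("n_particles must be non-negative")
        return cls(box_length=box_length, density=n_particles / box_length**2, **kw)

    @property
    def n_particles(self) -> int:
        return int(round(self.density * self.box_length**2))

    @property
    def persistence_time(self) -> float:
        """Orientational decorrelation time ``tau = 1 / D_r`` (inf if D_r = 0)."""
        if self.rot_diffusivity == 0:
            return math.inf
        return 1.0 / self.rot_diffusivity

    @property
    def persistence_length(self) -> float:
        """Distance travelled over one persistence time, ``v0 / D_r``."""
        if self.rot_diffusivity == 0:
            return math.inf
        return self.speed / self.rot_diffusivity

    @property
    def noise_amplitude(self) -> float:
        """Standard deviation of the per-step orientational kick."""
        return math.sqrt(2.0 * self.rot_diffusivity * self.dt)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the tabular Q-learning training protocol."""

    learning_rate: float = 0.01
    discount: float = 0.9
    reward_magnitude: float = 100.0
    episodes_per_cycle: int = 1000
    n_cycles: int = 303
    t_max: float = 6.0e4
    perception_time: float = 1.0
    scan_radius: float = 1.0
    goal_half_length: float = 12.5

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0.0 <= self.discount <= 1.0):
            raise ValueError("discount must be in [0, 1]")
        if self.episodes_per_cycle < 1 or self.n_cycles < 1:
            raise ValueError("episode and cycle counts must be >= 1")
        if self.t_max <= 0 or self.perception_time <= 0:
            raise ValueError("t_max and perception_time must be positive")
        if self.scan_radius <= 0:
            raise ValueError("scan_radius must be positive")
        if self.goal_half_length <= 0:
            raise ValueError("goal_half_length must be positive")

    def substeps(self, dt: float) -> int:
        """Integration substeps per decision epoch; ``perception_time`` must
        be an integer multiple of ``dt``."""
        m = self.perception_time / dt
        if abs(m - round(m)) > 1e-9 or round(m) < 1:
            raise ValueError(
                f"perception_time ({self.perception_time}) must be an integer "
                f"multiple of dt ({dt})"
            )
        return int(round(m))

    @property
    def max_epochs(self) -> int:
        return int(math.floor(self.t_max / self.perception_time + 1e-9))


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the non-reciprocal hitchhiking potential.

    The radial part is ``V0(r) = force_scale * friction * speed * R_s *
    (1 - R_s / r)`` for ``r_min <= r <= R_s`` and zero otherwise, so the
    mobility-normalised pull at contact distance ``r = R_s`` is
    ``force_scale * speed`` and the friction coefficient cancels from the
    overdamped dynamics.
    """

    speed: float = 1.5
    friction: float = 1.0
    scan_radius: float = 1.0
    r_min: float = 1.0 / 20.0
    force_scale: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_min < self.scan_radius):
            raise ValueError("need 0 < r_min < scan_radius")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.speed < 0 or self.force_scale <= 0:
            raise ValueError("speed must be >= 0 and force_scale > 0")

    @property
    def amplitude(self) -> float:
        """Potential prefactor ``force_scale * friction * speed * R_s``."""
        return self.force_scale * self.friction * self.speed * self.scan_radius


@dataclass(frozen=True)
class TheoryParams:
    """Inputs of the analytic partner-probability / drift theory."""

    density: float = 0.6
    box_length: float = 25.0
    scan_radius: float = 1.0
    go_angle: float = math.pi / 2.0
    perception_time: float = 1.0
    speed: float = 1.5
    rot_diffusivity: float = DEFAULT_ROT_DIFFUSIVITY

    def __post_init__(self) -> None:
        if self.density < 0 or self.box_length <= 0:
            raise ValueError("density must be >= 0 and box_length > 0")
        if math.pi * self.scan_radius**2 > self.box_length**2:
            raise ValueError("scan disk must fit inside the box area")
        if not (0.0 <= self.go_angle <= TWO_PI):
            raise ValueError("go_angle must lie in [0, 2*pi]")
        if self.perception_time <= 0 or self.speed < 0 or self.rot_diffusivity < 0:
            raise ValueError("invalid kinetic parameter")

    @property
    def n_particles(self) -> int:
        return int(round(self.density * self.box_length**2))

    @property
    def persistence_time(self) -> float:
        if self.rot_diffusivity == 0:
            return math.inf
        return 1.0 / self.rot_diffusivity
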