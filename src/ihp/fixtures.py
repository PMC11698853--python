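"""Deterministic scripted environments for tests and worked examples.

The fixtures replace the random bath by a handful of noiseless particles
whose evolution can be integrated by hand, plus one scripted two-state MDP
for checking the learner against exact Bellman values.  "Goalward" means
oriented along the navigation target (polar angle 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bath import BathState
from .params import BathParams
from .qlearn import TabularMDP

_ALIASES = {
    "single-upward-abp": "single-goalward-abp",
    "single-downward-abp": "single-antigoalward-abp",
}


@dataclass(frozen=True)
class ScriptedBathFixture:
    """A named deterministic bath configuration.

    ``noiseless`` flags particles whose orientational noise is switched off;
    with every particle noiseless the evolution is fully deterministic.
    """

    name: str
    positions: np.ndarray
    angles: np.ndarray
    noiseless: np.ndarray
    params: BathParams

    def to_state(self) -> BathState:
        return BathState(self.positions.copy(), self.angles.copy(), 0.0)

    def noise_scale(self) -> np.ndarray:
        """Per-particle orientational kick amplitudes (0 for noiseless)."""
        scale = np.full(len(self.angles), self.params.noise_amplitude)
        scale[self.noiseless] = 0.0
        return scale


def _single(name: str, angle: float, params: BathParams) -> ScriptedBathFixture:
    return ScriptedBathFixture(
        name=name,
        positions=np.array([[0.5, 0.0]]),
        angles=np.array([angle]),
        noiseless=np.array([True]),
        params=params,
    )


def make_fixture(name: str):
    """Return a fixture from the documented catalogue.

    - ``empty``: a bath with zero particles.
    - ``single-goalward-abp``: one noiseless particle 0.5 R_s ahead of the
      origin, oriented along the goal axis.
    - ``single-antigoalward-abp``: as above but oriented away from the goal.
    - ``circling-abp``: one noiseless chiral particle (D_r = 0, omega = 0.6)
      that closes a circle of radius v0/omega after 2*pi/omega.
    - ``toy-mdp``: deterministic two-state MDP with terminal rewards +/-100,
      for comparison against a value-iteration oracle.
    """
    name = _ALIASES.get(name, name)
    straight = BathParams.from_count(1, box_length=25.0, rot_diffusivity=0.0)
    if name == "empty":
        return ScriptedBathFixture(
            name="empty",
            positions=np.empty((0, 2)),
            angles=np.empty(0),
            noiseless=np.empty(0, bool),
            params=BathParams.from_count(0),
        )
    if name == "single-goalward-abp":
        return _single(name, 0.0, straight)
    if name == "single-antigoalward-abp":
        return _single(name, math.pi, straight)
    if name == "circling-abp":
        params = BathParams.from_count(
            1, box_length=25.0, rot_diffusivity=0.0, circ_frequency=0.6
        )
        # placed at the box centre so the whole orbit stays clear of the seam
        return ScriptedBathFixture(
            name=name,
            positions=np.array([[12.5, 12.5]]),
            angles=np.array([0.0]),
            noiseless=np.array([True]),
            params=params,
        )
    if name == "toy-mdp":
        # state 0: GO -> state 1 (r=0), NO GO -> crash (-100)
        # state 1: GO -> terminal goal (+100), NO GO -> back to state 0 (r=0)
        transitions = np.array([[-1, 1], [0, -1]])
        rewards = np.array([[-100.0, 0.0], [0.0, 100.0]])
        return TabularMDP(transitions=transitions, rewards=rewards, start_state=0)
    raise KeyError(f"unknown fixture {name!r}")
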