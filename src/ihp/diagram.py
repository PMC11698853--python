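"""Binary GO / NO-GO decision diagrams over discretised orientations.

The hitchhiker's state space discretises the partner's orientation into 360
one-degree bins; state ``mu`` (1-based) covers ``[(mu-1) deg, mu deg)``.
A fully trained agent is summarised by a binary mask over these bins, the
GO probability ``h_GO`` it was thresholded from, and the two descriptors of
the (largest) GO arc: the GO angle ``dphi`` (arc width) and the
anticipation angle ``phi0`` (arc centre, measured from the goal direction,
which lies along polar angle 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import TWO_PI

N_STATES = 360
BIN_WIDTH = TWO_PI / N_STATES


def angle_to_state(phi: float) -> int:
    """1-based state index of an orientation angle.

    ``mu = floor((phi mod 2*pi) / (2*pi/360)) + 1``; bin ``k`` covers
    ``[(k-1) deg, k deg)``, so ``phi = 0`` maps to state 1.
    """
    k = int(math.floor((phi % TWO_PI) / BIN_WIDTH))
    return min(k, N_STATES - 1) + 1


def wrap_to_pi(angle: float) -> float:
    """Wrap an angle to the half-open interval ``(-pi, pi]``."""
    r = angle % TWO_PI
    if r > math.pi:
        r -= TWO_PI
    return r


def extract_go_interval(go_mask: np.ndarray) -> tuple[float, float]:
    """Arc descriptors ``(phi0, dphi)`` of the longest circular GO run.

    Maximal circular runs of GO bins are found; the longest one (ties
    resolved in favour of the run whose midpoint is circularly closest to
    the goal direction 0) defines ``dphi`` = run length in radians and
    ``phi0`` = circular midpoint mapped to ``(-pi, pi]``.  An all-GO mask
    yields ``(0, 2*pi)``, an all-NO-GO mask ``(0, 0)``.
    """
    mask = np.asarray(go_mask, dtype=bool)
    if mask.shape != (N_STATES,):
        raise ValueError(f"go_mask must have shape ({N_STATES},)")
    if mask.all():
        return 0.0, TWO_PI
    if not mask.any():
        return 0.0, 0.0
    # rotate so the scan starts on a NO-GO bin, making runs contiguous
    start0 = int(np.flatnonzero(~mask)[0])
    runs: list[tuple[int, int]] = []  # (start bin 0-based, length)
    run_start, run_len = -1, 0
    for off in range(N_STATES):
        k = (start0 + off) % N_STATES
        if mask[k]:
            if run_len == 0:
                run_start = k
            run_len += 1
        elif run_len > 0:
            runs.append((run_start, run_len))
            run_len = 0
    if run_len > 0:
        runs.append((run_start, run_len))

    def midpoint(run: tuple[int, int]) -> float:
        s, n = run
        return wrap_to_pi((s + n / 2.0) * BIN_WIDTH)

    longest = max(n for _, n in runs)
    best = min(
        (r for r in runs if r[1] == longest),
        key=lambda r: (abs(midpoint(r)), r[0]),
    )
    return midpoint(best), longest * BIN_WIDTH


@dataclass
class DecisionDiagram:
    """Aggregated GO / NO-GO rule of a trained hitchhiker."""

    go_mask: np.ndarray
    go_probability: np.ndarray
    anticipation_angle: float
    go_angle: float
    n_cycles_aggregated: int = 1

    def __post_init__(self) -> None:
        self.go_mask = np.asarray(self.go_mask, dtype=bool)
        self.go_probability = np.asarray(self.go_probability, dtype=float)
        if self.go_mask.shape != (N_STATES,) or self.go_probability.shape != (N_STATES,):
            raise ValueError(f"masks must have shape ({N_STATES},)")

    def contains(self, phi: float) -> bool:
        """Whether orientation ``phi`` triggers a GO decision."""
        return bool(self.go_mask[angle_to_state(phi) - 1])

    @classmethod
    def from_mask(cls, go_mask: np.ndarray, n_cycles: int = 1) -> "DecisionDiagram":
        phi0, dphi = extract_go_interval(go_mask)
        return cls(go_mask, np.asarray(go_mask, float), phi0, dphi, n_cycles)

    @classmethod
    def from_interval(cls, anticipation_angle: float, go_angle: float) -> "DecisionDiagram":
        """Ideal diagram with a single GO arc of width ``go_angle`` centred
        at ``anticipation_angle``."""
        if not (0.0 <= go_angle <= TWO_PI):
            raise ValueError("go_angle must lie in [0, 2*pi]")
        centres = (np.arange(N_STATES) + 0.5) * BIN_WIDTH
        delta = np.abs(
            (centres - anticipation_angle + math.pi) % TWO_PI - math.pi
        )
        mask = delta <= go_angle / 2.0 + 1e-12
        if go_angle == 0.0:
            mask[:] = False
        return cls.from_mask(mask)


def aggregate_diagram(action_maps: np.ndarray | list, n_cycles: int | None = None) -> DecisionDiagram:
    """Combine per-cycle greedy action maps into the final decision diagram.

    ``action_maps`` is a (cycles, 360) array of 0 (NO GO) / 1 (GO) entries,
    tie states already realised as recorded random draws.  The pointwise GO
    probability is the relative GO frequency across cycles; states with
    ``h_GO >= 0.5`` form the GO mask.
    """
    maps = np.atleast_2d(np.asarray(action_maps, dtype=float))
    if maps.size == 0:
        raise ValueError("need at least one action map")
    if maps.shape[1] != N_STATES:
        raise ValueError(f"action maps must have {N_STATES} states")
    h_go = maps.mean(axis=0)
    mask = h_go >= 0.5
    phi0, dphi = extract_go_interval(mask)
    return DecisionDiagram(mask, h_go, phi0, dphi, n_cycles or maps.shape[0])
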