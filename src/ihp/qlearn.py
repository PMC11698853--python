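"""Tabular Q-learning for the hitchhiking agent.

The agent is motorless: every perception time ``tau_Q`` it inspects the
nearest bath particle within its scan radius and makes a binary decision —
GO (attach and share the particle's path for one epoch) or NO GO (rest).
The state is the partner's orientation, discretised into 360 one-degree
bins; the memory is a 360 x 2 table ``Q[mu, nu]`` with column 0 = NO GO and
column 1 = GO.  Rewards are only granted at the episode end: +R when the
agent has advanced half a box length along the goal axis, -R when it has
drifted half a box length backwards.

Update rule (applied once the next defined state ``mu'`` is observed, or
with a zero bootstrap at termination):

    Q[mu, nu] <- (1 - alpha) * Q[mu, nu] + alpha * (R + gamma * max_l Q[mu', l])
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .bath import BathState, init_bath
from .diagram import N_STATES, DecisionDiagram, aggregate_diagram
from .params import BathParams, TrainConfig

__all__ = [
    "new_qmatrix",
    "greedy_action",
    "epsilon_schedule",
    "q_update",
    "terminal_reward",
    "run_episode",
    "run_training_cycle",
    "train",
    "EpisodeRecord",
    "CycleResult",
    "TrainingResult",
    "TabularMDP",
    "q_learn_mdp",
]

N_ACTIONS = 2


def new_qmatrix() -> np.ndarray:
    """Zero-initialised 360 x 2 state-action value table."""
    return np.zeros((N_STATES, N_ACTIONS))


def greedy_action(q: np.ndarray, mu: int, rng: np.random.Generator) -> int:
    """Greedy action in 1-based state ``mu``; exact ties are a fair coin."""
    if not (1 <= mu <= N_STATES):
        raise ValueError(f"state must be in 1..{N_STATES}")
    row = q[mu - 1]
    if row[1] > row[0]:
        return 1
    if row[0] > row[1]:
        return 0
    return int(rng.random() < 0.5)


def epsilon_schedule(episode_index: int, episodes_per_cycle: int) -> float:
    """Exploration probability, linear from 1 (first episode) to 0 (last)."""
    if not (0 <= episode_index < episodes_per_cycle):
        raise ValueError("episode_index must satisfy 0 <= e < E")
    if episodes_per_cycle == 1:
        return 0.0
    return 1.0 - episode_index / (episodes_per_cycle - 1)


def q_update(
    q: np.ndarray,
    mu: int,
    nu: int,
    reward: float,
    mu_next: int | None,
    learning_rate: float = 0.01,
    discount: float = 0.9,
) -> np.ndarray:
    """Apply one tabular update in place (``mu_next=None`` marks an
    absorbing terminal state with zero bootstrap) and return ``q``."""
    if not (1 <= mu <= N_STATES) or nu not in (0, 1):
        raise ValueError("invalid state-action pair")
    bootstrap = 0.0 if mu_next is None else float(np.max(q[mu_next - 1]))
    q[mu - 1, nu] = (1.0 - learning_rate) * q[mu - 1, nu] + learning_rate * (
        reward + discount * bootstrap
    )
    return q


def terminal_reward(goal_coordinate: float, half_length: float, magnitude: float = 100.0) -> float:
    """Episode-end reward: +R at or beyond the goal edge, -R at or beyond
    the opposite edge, 0 in between."""
    if goal_coordinate >= half_length:
        return magnitude
    if goal_coordinate <= -half_length:
        return -magnitude
    return 0.0


@dataclass
class EpisodeRecord:
    """Per-episode summary and (optional) per-decision log."""

    outcome: int  # +1 goal, -1 opposite edge, 0 time limit
    n_epochs: int
    n_substeps: int
    duration: float
    final_position: np.ndarray
    epochs: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    states: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))  # 1-based
    actions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    random_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    partners: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_episode(
    bath_state: BathState,
    bath_params: BathParams,
    q: np.ndarray,
    cfg: TrainConfig,
    epsilon: float,
    rng: np.random.Generator,
    noise_scale: np.ndarray | None = None,
    record_log: bool = False,
) -> tuple[np.ndarray, EpisodeRecord]:
    """Run one training episode; ``q`` is updated in place and returned.

    The hitchhiker starts at the origin (tracked unwrapped); the provided
    bath state is consumed as the episode's initial condition and is not
    modified.  ``noise_scale`` optionally overrides the per-particle
    orientational noise amplitude (scripted fixtures).
    """
    m = cfg.substeps(bath_params.dt)
    n = bath_state.n_particles
    x = np.ascontiguousarray(bath_state.positions[:, 0], dtype=float) if n else np.empty(0)
    y = np.ascontiguousarray(bath_state.positions[:, 1], dtype=float) if n else np.empty(0)
    phi = np.ascontiguousarray(bath_state.angles, dtype=float)
    if noise_scale is None:
        sigma = np.full(n, bath_params.noise_amplitude)
    else:
        sigma = np.broadcast_to(np.asarray(noise_scale, float), (n,)).copy()
    max_epochs = cfg.max_epochs
    cap = max_epochs if record_log else 0
    log_epoch = np.empty(cap, np.int64)
    log_mu = np.empty(cap, np.int64)
    log_nu = np.empty(cap, np.int64)
    log_rand = np.empty(cap, np.int64)
    log_partner = np.empty(cap, np.int64)
    outcome, epochs, steps, n_log, ux, uy = kernels.train_episode_kernel(
        q,
        x,
        y,
        phi,
        sigma,
        bath_params.circ_frequency,
        bath_params.speed,
        bath_params.dt,
        bath_params.box_length,
        cfg.scan_radius,
        m,
        max_epochs,
        float(epsilon),
        cfg.learning_rate,
        cfg.discount,
        cfg.reward_magnitude,
        cfg.goal_half_length,
        _kernel_seed(rng),
        log_epoch,
        log_mu,
        log_nu,
        log_rand,
        log_partner,
    )
    rec = EpisodeRecord(
        outcome=outcome,
        n_epochs=epochs,
        n_substeps=steps,
        duration=steps * bath_params.dt,
        final_position=np.array([ux, uy]),
    )
    if record_log:
        rec.epochs = log_epoch[:n_log].copy()
        rec.states = log_mu[:n_log] + 1
        rec.actions = log_nu[:n_log].copy()
        rec.random_flags = log_rand[:n_log].astype(bool)
        rec.partners = log_partner[:n_log].copy()
    return q, rec


@dataclass
class CycleResult:
    """Outcome of one training cycle (a fresh Q table trained to greed)."""

    q: np.ndarray
    action_map: np.ndarray  # (360,) greedy actions, ties realised randomly
    tie_mask: np.ndarray  # states whose greedy action was a recorded draw
    durations: np.ndarray  # per-episode duration in time units
    outcomes: np.ndarray  # per-episode +1 / -1 / 0
    seed: int


def run_training_cycle(
    cfg: TrainConfig,
    bath_params: BathParams,
    seed: int,
    episodes: int | None = None,
) -> CycleResult:
    """Train a zero-initialised Q table for one cycle.

    Each episode re-draws a homogeneous bath and anneals the exploration
    probability linearly across the cycle.  Sub-streams are derived from
    ``seed`` and the episode index, so cycles are individually reproducible.
    """
    n_episodes = cfg.episodes_per_cycle if episodes is None else int(episodes)
    q = new_qmatrix()
    durations = np.empty(n_episodes)
    outcomes = np.empty(n_episodes, np.int64)
    for e in range(n_episodes):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0, e))))
        state = init_bath(bath_params, rng)
        eps = epsilon_schedule(e, n_episodes)
        _, rec = run_episode(state, bath_params, q, cfg, eps, rng)
        durations[e] = rec.duration
        outcomes[e] = rec.outcome
    tie_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 1))))
    tie_mask = q[:, 0] == q[:, 1]
    action_map = (q[:, 1] > q[:, 0]).astype(np.int64)
    action_map[tie_mask] = tie_rng.integers(0, 2, size=int(tie_mask.sum()))
    return CycleResult(q, action_map, tie_mask, durations, outcomes, seed)


@dataclass
class TrainingResult:
    """Repeated-training outcome: per-cycle maps plus the aggregate rule."""

    diagram: DecisionDiagram
    action_maps: np.ndarray  # (cycles, 360)
    cycle_seeds: np.ndarray
    mean_durations: np.ndarray  # per-cycle mean episode duration
    success_rates: np.ndarray  # per-cycle fraction of goal-reaching episodes
    last_cycle: CycleResult | None = None


def train(
    bath_params: BathParams,
    cfg: TrainConfig,
    seed: int,
    n_cycles: int | None = None,
) -> TrainingResult:
    """Run ``n_cycles`` independent training cycles and aggregate their
    greedy action maps into the final decision diagram."""
    n_cycles = cfg.n_cycles if n_cycles is None else int(n_cycles)
    maps = np.empty((n_cycles, N_STATES), np.int64)
    seeds = np.empty(n_cycles, np.int64)
    mean_dur = np.empty(n_cycles)
    succ = np.empty(n_cycles)
    last = None
    for c in range(n_cycles):
        cseed = int(np.random.SeedSequence((seed, c)).generate_state(1)[0] & 0x7FFFFFFF)
        res = run_training_cycle(cfg, bath_params, cseed)
        maps[c] = res.action_map
        seeds[c] = cseed
        mean_dur[c] = res.durations.mean()
        succ[c] = (res.outcomes == 1).mean()
        last = res
    return TrainingResult(aggregate_diagram(maps), maps, seeds, mean_dur, succ, last)


# --------------------------------------------------------------------------
# Small deterministic MDPs: the same update/exploration machinery exercised
# on scripted transition tables, so the learner can be checked against exact
# Bellman solutions.

@dataclass(frozen=True)
class TabularMDP:
    """Deterministic episodic MDP with integer states and two actions.

    ``transitions[s, a]`` is the successor state or -1 for termination;
    ``rewards[s, a]`` is granted on taking the step.
    """

    transitions: np.ndarray
    rewards: np.ndarray
    start_state: int = 0

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]


def q_learn_mdp(
    mdp: TabularMDP,
    n_episodes: int,
    rng: np.random.Generator,
    learning_rate: float = 0.01,
    discount: float = 0.9,
    max_steps: int = 100,
) -> np.ndarray:
    """Train a small Q table on a scripted MDP with the agent's own
    epsilon-greedy schedule and update rule."""
    q = np.zeros((mdp.n_states, 2))
    for e in range(n_episodes):
        eps = epsilon_schedule(e, n_episodes)
        s = mdp.start_state
        for _ in range(max_steps):
            if rng.random() < eps:
                a = int(rng.random() < 0.5)
            elif q[s, 1] > q[s, 0]:
                a = 1
            elif q[s, 0] > q[s, 1]:
                a = 0
            else:
                a = int(rng.random() < 0.5)
            s_next = int(mdp.transitions[s, a])
            r = float(mdp.rewards[s, a])
            bootstrap = 0.0 if s_next < 0 else float(q[s_next].max())
            q[s, a] = (1 - learning_rate) * q[s, a] + learning_rate * (r + discount * bootstrap)
            if s_next < 0:
                break
            s = s_next
    return q
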