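"""Shared fixtures: trained diagrams and trajectory ensembles.

Training is the expensive part of the suite, so fully trained agents are
built once per session and shared.  Every training uses the standard cycle
length (1000 episodes); the number of repeated cycles is reduced relative
to a production run, which widens the sampling noise of the aggregated
diagrams but does not bias them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ihp import BathParams, TrainConfig, simulate_q_ihp, train

LOW_DR = 6.0e-3 * math.pi**2
HIGH_DR = 6.0e-2 * math.pi**2

#: circular frequencies (per tau_Q) of the chiral training sweep
OMEGA_GRID = 0.36 * math.pi * np.array([-1.0, -0.5, 0.25, 0.625, 1.0])


@pytest.fixture(scope="session")
def trained_low_dr():
    """50 training cycles in the weakly diffusive achiral bath."""
    return train(BathParams(rot_diffusivity=LOW_DR), TrainConfig(), seed=101, n_cycles=50)


@pytest.fixture(scope="session")
def trained_high_dr():
    """10 training cycles in a ten-fold less persistent achiral bath."""
    return train(BathParams(rot_diffusivity=HIGH_DR), TrainConfig(), seed=202, n_cycles=10)


@pytest.fixture(scope="session")
def chiral_sweep():
    """Aggregated diagrams across the chiral-frequency grid (8 cycles each)."""
    out = []
    for i, omega in enumerate(OMEGA_GRID):
        bath = BathParams(rot_diffusivity=LOW_DR, circ_frequency=float(omega))
        res = train(bath, TrainConfig(), seed=1000 + i, n_cycles=8)
        out.append((float(omega), res.diagram))
    return out


@pytest.fixture(scope="session")
def q_ensemble(trained_low_dr):
    """200 greedy-hitchhiker runs of 100 persistence times each."""
    bath = BathParams(rot_diffusivity=LOW_DR)
    duration = round(100.0 * bath.persistence_time)  # 1689 tau_Q
    runs = []
    for r in range(200):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((555, r))))
        runs.append(simulate_q_ihp(trained_low_dr.diagram, bath, duration, rng))
    return runs
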