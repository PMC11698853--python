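"""Compiled inner loops for training and trajectory generation.

These kernels are private plumbing: the public wrappers in
:mod:`ihp.qlearn` and :mod:`ihp.models` own argument validation, state
containers and seeding.  All kernels mutate the bath arrays in place and
use numba's global NumPy random stream, seeded explicitly per call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 6.283185307179586
N_STATES = 360
_BIN = TWO_PI / N_STATES


@njit(cache=True, fastmath=True, inline="always")
def _min_image(d, box):
    if d > 0.5 * box:
        return d - box
    if d < -0.5 * box:
        return d + box
    return d


@njit(cache=True, fastmath=True, inline="always")
def _state_of(phi):
    k = int((phi % TWO_PI) / _BIN)
    if k > N_STATES - 1:
        k = N_STATES - 1
    return k


@njit(cache=True, fastmath=True, inline="always")
def _advance_bath(x, y, phi, sigma, omega, v0, dt, box):
    # translation from the pre-step angle, then the orientational kick
    n = x.shape[0]
    eta = np.random.standard_normal(n)
    for j in range(n):
        xx = x[j] + v0 * dt * np.cos(phi[j])
        yy = y[j] + v0 * dt * np.sin(phi[j])
        if xx >= box:
            xx -= box
        elif xx < 0.0:
            xx += box
        if yy >= box:
            yy -= box
        elif yy < 0.0:
            yy += box
        x[j] = xx
        y[j] = yy
        # per-step angle increment is far below 2*pi, one fold-back suffices
        ph = phi[j] + omega * dt + sigma[j] * eta[j]
        if ph >= TWO_PI:
            ph -= TWO_PI
        elif ph < 0.0:
            ph += TWO_PI
        phi[j] = ph


@njit(cache=True, fastmath=True, inline="always")
def _nearest(wx, wy, x, y, box):
    best = -1
    bd2 = 1.0e300
    for j in range(x.shape[0]):
        dx = _min_image(x[j] - wx, box)
        dy = _min_image(y[j] - wy, box)
        d2 = dx * dx + dy * dy
        if d2 < bd2:
            bd2 = d2
            best = j
    return best, bd2


@njit(cache=True, fastmath=True)
def train_episode_kernel(
    q,
    x,
    y,
    phi,
    sigma,
    omega,
    v0,
    dt,
    box,
    rs,
    m,
    max_epochs,
    eps,
    alpha,
    gamma,
    rmag,
    half_len,
    seed,
    log_epoch,
    log_mu,
    log_nu,
    log_rand,
    log_partner,
):
    """One training episode; returns (outcome, epochs, substeps, n_logged, x, y).

    outcome: +1 goal reached, -1 opposite edge hit, 0 time limit.
    The Q table and the bath arrays are updated in place; decisions are
    appended to the log arrays when they have non-zero length.
    """
    np.random.seed(seed)
    record = log_epoch.shape[0] > 0
    rs2 = rs * rs
    ux = 0.0  # unwrapped hitchhiker position; goal axis is x
    uy = 0.0
    pend_mu = -1
    pend_nu = 0
    n_log = 0
    steps = 0
    for epoch in range(max_epochs):
        wx = ux % box
        wy = uy % box
        attached = False
        partner = -1
        if x.shape[0] > 0:
            j, d2 = _nearest(wx, wy, x, y, box)
            if d2 <= rs2:
                mu = _state_of(phi[j])
                if pend_mu >= 0:
                    # deferred bootstrap of the previous decision, reward 0
                    mq = q[mu, 0]
                    if q[mu, 1] > mq:
                        mq = q[mu, 1]
                    q[pend_mu, pend_nu] = (1.0 - alpha) * q[pend_mu, pend_nu] + alpha * gamma * mq
                if np.random.random() < eps:
                    nu = 1 if np.random.random() < 0.5 else 0
                    was_random = 1
                else:
                    was_random = 0
                    if q[mu, 1] > q[mu, 0]:
                        nu = 1
                    elif q[mu, 0] > q[mu, 1]:
                        nu = 0
                    else:
                        nu = 1 if np.random.random() < 0.5 else 0
                pend_mu = mu
                pend_nu = nu
                if record:
                    log_epoch[n_log] = epoch
                    log_mu[n_log] = mu
                    log_nu[n_log] = nu
                    log_rand[n_log] = was_random
                    log_partner[n_log] = j
                    n_log += 1
                if nu == 1:
                    ux += _min_image(x[j] - wx, box)
                    uy += _min_image(y[j] - wy, box)
                    attached = True
                    partner = j
                    if ux >= half_len or ux <= -half_len:
                        r = rmag if ux >= half_len else -rmag
                        q[pend_mu, pend_nu] = (1.0 - alpha) * q[pend_mu, pend_nu] + alpha * r
                        return (1 if ux >= half_len else -1), epoch + 1, steps, n_log, ux, uy
        for k in range(m):
            pdx = 0.0
            pdy = 0.0
            if attached:
                pdx = v0 * dt * np.cos(phi[partner])
                pdy = v0 * dt * np.sin(phi[partner])
            _advance_bath(x, y, phi, sigma, omega, v0, dt, box)
            steps += 1
            if attached:
                ux += pdx
                uy += pdy
                if ux >= half_len or ux <= -half_len:
                    r = rmag if ux >= half_len else -rmag
                    q[pend_mu, pend_nu] = (1.0 - alpha) * q[pend_mu, pend_nu] + alpha * r
                    return (1 if ux >= half_len else -1), epoch + 1, steps, n_log, ux, uy
    return 0, max_epochs, steps, n_log, ux, uy


@njit(cache=True, fastmath=True)
def simulate_q_kernel(
    go,
    x,
    y,
    phi,
    sigma,
    omega,
    v0,
    dt,
    box,
    rs,
    m,
    n_epochs,
    seed,
    traj_x,
    traj_y,
    ep_attached,
    ep_partner,
):
    """Greedy hitchhiker driven by a fixed GO mask; no learning, no goal.

    Fills per-substep unwrapped trajectory arrays (length n_epochs*m + 1)
    and per-epoch attachment flags / partner indices.
    """
    np.random.seed(seed)
    rs2 = rs * rs
    ux = 0.0
    uy = 0.0
    traj_x[0] = 0.0
    traj_y[0] = 0.0
    idx = 0
    for epoch in range(n_epochs):
        wx = ux % box
        wy = uy % box
        attached = False
        partner = -1
        if x.shape[0] > 0:
            j, d2 = _nearest(wx, wy, x, y, box)
            if d2 <= rs2 and go[_state_of(phi[j])]:
                ux += _min_image(x[j] - wx, box)
                uy += _min_image(y[j] - wy, box)
                attached = True
                partner = j
        ep_attached[epoch] = attached
        ep_partner[epoch] = partner
        for k in range(m):
            pdx = 0.0
            pdy = 0.0
            if attached:
                pdx = v0 * dt * np.cos(phi[partner])
                pdy = v0 * dt * np.sin(phi[partner])
            _advance_bath(x, y, phi, sigma, omega, v0, dt, box)
            if attached:
                ux += pdx
                uy += pdy
            idx += 1
            traj_x[idx] = ux
            traj_y[idx] = uy


@njit(cache=True, fastmath=True)
def simulate_potential_kernel(
    go,
    x,
    y,
    phi,
    sigma,
    omega,
    v0,
    dt,
    box,
    rs,
    rmin,
    fscale,
    n_steps,
    seed,
    traj_x,
    traj_y,
):
    """Potential-driven hitchhiker pulled by every in-range GO particle.

    At each step the bath advances first; the hitchhiker displacement is
    dt times the summed mobility-normalised pulls fscale*v0*rs^2/r^2 and is
    capped at the distance to the nearest contributing particle so that it
    can never overshoot past its closest attractor.
    """
    np.random.seed(seed)
    rs2 = rs * rs
    rmin2 = rmin * rmin
    ux = 0.0
    uy = 0.0
    traj_x[0] = 0.0
    traj_y[0] = 0.0
    for step in range(n_steps):
        _advance_bath(x, y, phi, sigma, omega, v0, dt, box)
        wx = ux % box
        wy = uy % box
        vx = 0.0
        vy = 0.0
        dnear = 1.0e300
        for j in range(x.shape[0]):
            dx = _min_image(x[j] - wx, box)
            dy = _min_image(y[j] - wy, box)
            r2 = dx * dx + dy * dy
            if r2 < rmin2 or r2 > rs2:
                continue
            if not go[_state_of(phi[j])]:
                continue
            r = np.sqrt(r2)
            mag = fscale * v0 * rs2 / r2
            vx += mag * dx / r
            vy += mag * dy / r
            if r < dnear:
                dnear = r
        sx = vx * dt
        sy = vy * dt
        s2 = sx * sx + sy * sy
        if s2 > dnear * dnear:
            sc = dnear / np.sqrt(s2)
            sx *= sc
            sy *= sc
        ux += sx
        uy += sy
        traj_x[step + 1] = ux
        traj_y[step + 1] = uy
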