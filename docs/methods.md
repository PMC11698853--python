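# Methods

This note documents the models implemented in `ihp`, the choices that were
genuinely open, and what the package's tests do and do not demonstrate.

## The bath

The environment is a two-dimensional periodic box of side `L` containing
`N = round(rho * L**2)` non-interacting active Brownian particles (ABPs).
Each particle moves at constant speed `v0` along its orientation
`u_i = (cos phi_i, sin phi_i)`; the orientation undergoes rotational
diffusion with diffusivity `D_r` and, for chiral particles (cABPs), an
additional constant angular drift `omega`:

    dr_i/dt   = v0 u_i(t)
    dphi_i/dt = xi_i(t) + omega,      <xi_i(t) xi_j(t')> = 2 D_r delta_ij delta(t-t')

Translational diffusion is neglected.  The equations are integrated with a
forward Euler–Maruyama scheme of step `dt`: the translation uses the
pre-step orientation, then the orientational kick is drawn.  Orientations
decorrelate over the persistence time `tau = 1/D_r` (reported as infinite
for `D_r = 0`), and the persistence length is `l_p = v0 / D_r`.

Units: the hitchhiker's scan radius `R_s` is the length unit and its
perception time `tau_Q` the time unit.  Defaults follow the standard
setting of the model: `v0 = 1.5 R_s/tau_Q`, `dt = tau_Q/6`, `L = 25 R_s`,
`rho = 0.6 / R_s**2` and `D_r = 6 pi^2 1e-3 / tau_Q` unless varied.
Initial conditions are uniform positions and orientations — the
maximum-entropy choice for a homogeneous bath.

**Coordinate convention.** The navigation goal lies along the positive-x
axis, i.e. along polar angle 0, half a box length from the agent's start.
With this choice "orientation angle of a partner" and "angle relative to
the goal" coincide, so the anticipation angle of a trained agent in an
achiral bath is zero by symmetry and all arc descriptors are measured
directly in the simulation frame.

## The Q-learning hitchhiker

The hitchhiker (IHP) has no propulsion.  Every `tau_Q` it locates the
nearest bath particle by minimum-image distance.  If none lies within
`R_s` no state is defined, nothing is learned, and the agent rests.
Otherwise the partner's orientation, discretised into 360 one-degree bins,
is the state `mu`, and the agent picks one of two actions: GO (share the
partner's path for the coming epoch) or NO GO (rest, detaching if
necessary).  Attachment is literal: on GO the agent's position is set to
the partner's, which includes an initial jump of at most `R_s`, and it
then copies the partner's displacement every `dt` until the next decision.
The agent's own position is tracked unwrapped so that progress toward the
goal at `x = L/2` is well defined; the box periodicity only wraps the bath.

The memory is a 360x2 table updated by

    Q[mu, nu] <- (1 - alpha) Q[mu, nu] + alpha (R + gamma max_l Q[mu', l])

with `alpha = 0.01` and `gamma = 0.9`.  `R = +-100` is granted only when
the episode terminates at the goal edge (`x >= L/2`) or the opposite edge
(`x <= -L/2`), with a zero bootstrap (absorbing state); all intermediate
updates carry `R = 0`.  If the epoch after a decision has no particle in
range, the pending update is deferred until the next defined state.
Episodes start at the origin in a freshly drawn bath, end at either edge
or at `t_max = 6e4 tau_Q`, and are annealed with an exploration
probability decreasing linearly from 1 to 0 over the cycle; exploratory
decisions update the table like greedy ones.  Exact value ties resolve by
a fair coin.

A cycle is 1000 such episodes on a zero-initialised table.  Because single
cycles retain sampling noise (neighbouring states can disagree), the final
decision rule aggregates many independent cycles: the GO probability
`h_GO(mu)` is the fraction of cycles whose greedy action in `mu` is GO
(ties realised as recorded draws), and states with `h_GO >= 0.5` form the
GO mask.  The longest circular GO run defines the GO angle `dphi` (arc
width) and the anticipation angle `phi0` (arc centre in `(-pi, pi]`,
ties between equally long runs resolved toward the goal direction).

## The potential hitchhiker

The learned rule transfers to a purely physical model: a non-reciprocal
attractive potential

    V(r, phi) = V0(r) if phi in the GO arc, else 0
    V0(r) = 5 gamma_f v0 R_s (1 - R_s / r),   R_min <= r <= R_s

with friction coefficient `gamma_f` (which cancels from the overdamped
dynamics) and lower cut-off `R_min = R_s / 20` preventing force
divergence.  The agent feels every in-range favourably oriented particle
at once — mobility-normalised pull `5 v0 R_s^2 / r^2` toward each — and
has no perception time.  Within a step the bath advances first; the
agent's displacement then uses the post-step bath (an O(dt) convention).
A finite step could overshoot past an attractor, so the displacement is
rescaled, direction unchanged, to the distance to the nearest contributing
particle whenever it exceeds it.  Particles closer than `R_min` exert no
pull: an agent that close is considered attached and simply rests until
the next kick.

## Partner-probability and drift theory

With `N` particles uniform in the box, the probability that the agent's
scan disk holds at least one particle is `1 - (1 - pi R_s^2/L^2)**N`; the
nearest one points into a GO arc of width `dphi` with probability
`dphi / 2 pi`, giving the instantaneous partner probability `p(0)`
(`p0` in the API).  Treating successive decision epochs as independent
draws — reasonable because a particle travels `1.5 R_s` per epoch, largely
refreshing the scan disk — the chance of having found a first partner by
time `t` is `p(t) = 1 - (1 - p(0))**(floor(t/tau_Q) + 1)`.  `p(t)` upper-
bounds the probability of currently holding a partner, since partners are
also lost.

The drift description sets the hitchhiking velocity to `v_H(t) = p(t) v0`.
The short-time curve squares its exact integral over the piecewise-
constant epochs, `MSD_0(t) = (v0 int_0^t p)^2`; the long-time curve is
ballistic with the drift speed averaged over one bath persistence time,
`v_inf = (v0/tau) int_0^tau p`, so `MSD_inf(t) = (v_inf t)^2`.  For the
potential variant the agent responds to *all* suitable particles, so the
counterpart probability is
`p0_potential = 1 - (1 - (pi R_s^2/L^2)(dphi/2 pi))**N >= p0`; it tends to
1 at high density for any arc, while `p0` saturates at `dphi/2 pi`.

**Known biases of the drift reconstruction.**  `MSD_0` is the squared
*mean* drift of a Bernoulli mixture: the actual mean-square displacement
at `t <= tau_Q` is `p(0) (v0 t)^2` plus the attachment-jump contribution,
both larger, so `MSD_0` is a short-time lower bound.  Conversely `v_inf`
ignores the directional spread of partners across the GO arc and the
waiting episodes between partners, so `MSD_inf` bounds the late-time MSD
from above; in the package's own ensembles at `rho = 0.6` the simulated
late-time MSD is roughly half the predicted `MSD_inf`, with the ballistic
exponent itself reproduced to within a few percent.  The tests assert
exactly these bound properties rather than pointwise agreement.

## Problem sizes and what the tests show

Production-quality strategy estimates aggregate hundreds of cycles; the
package's default verification uses the full cycle length of 1000
episodes throughout and scales down only the number of repeated cycles
and ensemble runs: 50 cycles for the achiral reference diagram, 8–10
cycles per parameter point in sweeps, 120–200 trajectory runs for MSD
curves and 400–500 paired runs for the model comparison.  Cycle length is
kept at full scale deliberately: truncated cycles stop before the
exploitation phase anneals, which measurably biases the aggregated arc
(wider `dphi`, overshooting `|phi0|`).  At these sizes the anticipation
slope carries a sampling spread of a few hundredths; quantitative checks
use tolerances wide enough for that spread, and monotonicity / sign /
bound checks are robust to it.

The synthetic bath realises exactly the idealised model: non-interacting
partners, no translational noise, no inertia, no back-reaction on the
bath.  Passing tests therefore validate the algorithms and the theory in
their own setting; they do not speak to crowded or interacting baths,
where collective structure would alter both the learned rule and the
partner statistics.

## Numerical notes

- The closed-form ABP mean-squared displacement uses `expm1` to avoid
  cancellation in the ballistic limit.  The Euler–Maruyama discretisation
  bias of the simulated MSD at `dt = tau_Q/6` is of order 1e-5 relative —
  far below the sampling error of any ensemble used here.
- Orientations are stored wrapped to `[0, 2 pi)`; a single conditional
  fold-back suffices per step because per-step increments are far below a
  full turn.  State binning guards the `k = 360` edge case produced by
  floating-point rounding just below `2 pi`.
- Compiled kernels (numba) draw noise from numpy's global legacy stream,
  seeded per episode/run from a `SeedSequence` of the user seed and the
  episode index, so runs are bitwise reproducible while episodes stay
  statistically independent.  Python-level code uses `numpy.random.Generator`.
- Exact Q-value ties (untrained states) are broken by a fair coin from the
  run's own stream and recorded, so aggregated diagrams are reproducible.
- The greedy trajectory recorder samples positions after every `dt`
  substep; the attachment jump of epoch `n` therefore appears between the
  last sample of epoch `n-1` and the first of epoch `n`, consistent with
  starting every run at the origin.

## Limitations

- The decision-state discretisation is fixed at 360 bins; much coarser
  bins would blur the arc edges, much finer ones would slow convergence.
- The chiral bath's closed-form MSD is not implemented; the closed form is
  only used (and only valid) for achiral particles.
- The cumulative probability `p(t)` assumes epoch independence; at very
  low speeds or very small boxes, scan-disk contents correlate between
  epochs and `p(t)` loses accuracy.
- Training at extreme persistence (`l_p >> L`) explores partner changes so
  rarely that the learned arc is no longer comparable across `D_r`; the
  monotonicity of `dphi` in `D_r` is asserted away from that regime.
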