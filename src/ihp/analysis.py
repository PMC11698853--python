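"""Ensemble statistics and the analytic drift description of hitchhiking.

The theory rests on the probability that a suitable travel partner is
available.  With ``N = rho * L**2`` particles placed uniformly in the
periodic box, the chance that at least one sits inside the scan disk and
that the nearest one points into the GO arc of width ``dphi`` is

    p(0) = (1 - (1 - pi R_s^2 / L^2)**N) * dphi / (2 pi).

Treating successive decision epochs as independent draws gives the
cumulative probability of having found the first partner by time ``t``,

    p(t) = 1 - (1 - p(0))**(floor(t / tau_Q) + 1),

which upper-bounds the probability of currently holding a partner.  The
drift reconstruction squares the integrated mean hitchhiking velocity
``v_H(t) = p(t) v0`` for the short-time curve and uses the average of
``p(t) v0`` over one bath persistence time as the asymptotic drift speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import IHPTrajectory
from .params import TWO_PI, TheoryParams

__all__ = [
    "MSDCurve",
    "ensemble_msd",
    "attachment_fraction",
    "p0",
    "p0_potential",
    "p_of_t",
    "msd_theory",
    "fit_phi0_slope",
    "fit_dphi_vs_dr",
    "loglog_slope",
]


@dataclass
class MSDCurve:
    """Ensemble mean-squared displacement on a shared time grid."""

    times: np.ndarray
    msd: np.ndarray
    stderr: np.ndarray
    n_runs: int


def ensemble_msd(trajectories: list[IHPTrajectory] | np.ndarray) -> MSDCurve:
    """MSD(t) = < |r(t) - r(0)|^2 > over an ensemble of unwrapped runs.

    Accepts a list of :class:`IHPTrajectory` on identical grids or a plain
    ``(runs, T, 2)`` position array (then the grid index is the time).
    """
    if isinstance(trajectories, np.ndarray):
        pos = trajectories
        times = np.arange(pos.shape[1], dtype=float)
    else:
        if len(trajectories) == 0:
            raise ValueError("need at least one trajectory")
        times = trajectories[0].times
        for tr in trajectories[1:]:
            if len(tr.times) != len(times) or not np.allclose(tr.times, times):
                raise ValueError("trajectories must share one time grid")
        pos = np.stack([tr.positions for tr in trajectories])
    disp = pos - pos[:, :1, :]
    sq = np.einsum("rti,rti->rt", disp, disp)
    n = sq.shape[0]
    msd = sq.mean(axis=0)
    stderr = sq.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(msd)
    return MSDCurve(np.asarray(times, float), msd, stderr, n)


def attachment_fraction(trajectories: list[IHPTrajectory]) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of runs holding a travel partner at each decision epoch.

    Returns ``(epoch_times, fraction)``; requires decision-logging
    trajectories from the Q-variant.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    flags = np.stack([tr.epoch_attached for tr in trajectories])
    if flags.size == 0:
        raise ValueError("trajectories carry no decision logs")
    tau = trajectories[0].perception_time
    times = np.arange(flags.shape[1]) * tau
    return times, flags.mean(axis=0)


def p0(tp: TheoryParams) -> float:
    """Probability of an instantaneously suitable partner for the
    decision-driven hitchhiker (nearest-particle focus)."""
    area_frac = math.pi * tp.scan_radius**2 / tp.box_length**2
    return (1.0 - (1.0 - area_frac) ** tp.n_particles) * tp.go_angle / TWO_PI


def p0_potential(tp: TheoryParams, effective_scan_radius: float | None = None) -> float:
    """Probability that at least one particle is simultaneously in range
    *and* favourably oriented — the partner probability of the potential
    variant, which is pulled by every suitable particle at once.

    ``effective_scan_radius`` optionally shrinks the perception range to
    mimic the looser coupling of the potential model.
    """
    rs = tp.scan_radius if effective_scan_radius is None else effective_scan_radius
    if rs < 0 or math.pi * rs**2 > tp.box_length**2:
        raise ValueError("scan disk must fit inside the box")
    single = (math.pi * rs**2 / tp.box_length**2) * tp.go_angle / TWO_PI
    return 1.0 - (1.0 - single) ** tp.n_particles


def p_of_t(tp: TheoryParams, t: np.ndarray) -> np.ndarray:
    """Cumulative first-partner probability on a time grid: one independent
    chance ``p0`` per decision epoch, including the epoch at ``t = 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    n_chances = np.floor(t / tp.perception_time).astype(int) + 1
    return 1.0 - (1.0 - p0(tp)) ** n_chances


def _integral_p(t: float, p_zero: float, tau_q: float) -> float:
    """Exact integral of the piecewise-constant p(t') over [0, t]."""
    if p_zero <= 0.0:
        return 0.0
    if p_zero >= 1.0:
        return t
    k = int(math.floor(t / tau_q))
    frac = t - k * tau_q
    f = 1.0 - p_zero
    # sum of p over k full epochs: tau_q * (k - f*(1-f^k)/p0)
    full = tau_q * (k - f * (1.0 - f**k) / p_zero)
    return full + frac * (1.0 - f ** (k + 1))


def msd_theory(tp: TheoryParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Short-time and long-time drift predictions on the grid ``t``.

    ``msd_short(t) = (v0 * int_0^t p)^2`` integrates the time-dependent
    drift exactly over the piecewise-constant epochs; ``msd_long(t) =
    (v_inf * t)^2`` uses the drift speed ``v_inf`` obtained by averaging
    ``p(t') v0`` over one bath persistence time.
    """
    t = np.asarray(t, dtype=float)
    pz = p0(tp)
    tau_q = tp.perception_time
    integrals = np.array([_integral_p(float(ti), pz, tau_q) for ti in t])
    msd_short = (tp.speed * integrals) ** 2
    tau = tp.persistence_time
    if math.isinf(tau):
        v_inf = tp.speed if pz > 0 else 0.0
    else:
        v_inf = tp.speed * _integral_p(tau, pz, tau_q) / tau
    msd_long = (v_inf * t) ** 2
    return msd_short, msd_long


def fit_phi0_slope(
    omegas: np.ndarray, phi0s: np.ndarray, perception_time: float = 1.0
) -> float:
    """Least-squares slope of the anticipation angle against ``omega tau_Q``
    through the origin (symmetry forces ``phi0(0) = 0``)."""
    x = np.asarray(omegas, dtype=float) * perception_time
    yv = np.asarray(phi0s, dtype=float)
    if x.shape != yv.shape or len(np.unique(x)) < 2:
        raise ValueError("need phi0 values at >= 2 distinct frequencies")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("degenerate design: all frequencies are zero")
    return float(x @ yv) / sxx


def fit_dphi_vs_dr(drs: np.ndarray, dphis: np.ndarray) -> tuple[float, float, float]:
    """Least-squares coefficients (a, b, c) of the empirical trend
    ``dphi = a + b * D_r + c / D_r`` across rotational diffusivities."""
    dr = np.asarray(drs, dtype=float)
    dphi = np.asarray(dphis, dtype=float)
    if np.any(dr <= 0):
        raise ValueError("all rotational diffusivities must be positive")
    if len(np.unique(dr)) < 3:
        raise ValueError("need >= 3 distinct diffusivities")
    design = np.column_stack((np.ones_like(dr), dr, 1.0 / dr))
    coef, *_ = np.linalg.lstsq(design, dphi, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def loglog_slope(curve: MSDCurve, window: tuple[float, float]) -> float:
    """Power-law exponent of the MSD over a time window, from a straight
    line fit in log-log coordinates."""
    lo, hi = window
    sel = (curve.times >= lo) & (curve.times <= hi) & (curve.times > 0)
    if sel.sum() < 2:
        raise ValueError("window must contain >= 2 positive-time points")
    if np.any(curve.msd[sel] <= 0):
        raise ValueError("msd must be positive inside the window")
    slope, _ = np.polyfit(np.log(curve.times[sel]), np.log(curve.msd[sel]), 1)
    return float(slope)
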