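"""Ensemble statistics, partner-probability theory and fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihp import (
    IHPTrajectory,
    TheoryParams,
    attachment_fraction,
    ensemble_msd,
    fit_dphi_vs_dr,
    fit_phi0_slope,
    loglog_slope,
    msd_theory,
    p0,
    p0_potential,
    p_of_t,
)


def _traj(positions):
    positions = np.asarray(positions, float)
    return IHPTrajectory(np.arange(len(positions), dtype=float), positions)


class TestEnsembleMSD:
    def test_stationary_runs_give_zero(self):
        runs = [_traj(np.zeros((10, 2))) for _ in range(4)]
        curve = ensemble_msd(runs)
        assert np.all(curve.msd == 0.0)

    def test_uniform_drift_gives_v0t_squared(self):
        v0 = 1.5
        t = np.arange(10, dtype=float)
        pos = np.column_stack((v0 * t, np.zeros_like(t)))
        curve = ensemble_msd([_traj(pos)] * 3)
        np.testing.assert_allclose(curve.msd, (v0 * t) ** 2)
        assert np.all(curve.stderr == 0.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([_traj(np.zeros((5, 2))), _traj(np.zeros((7, 2)))])
        with pytest.raises(ValueError):
            ensemble_msd([])


class TestPartnerProbability:
    def test_zero_go_angle_gives_zero(self):
        assert p0(TheoryParams(go_angle=0.0)) == 0.0

    def test_reference_value_at_standard_bath(self):
        # rho=0.6, L=25, dphi=pi/2; frozen from the closed form, which was
        # cross-checked against a Monte-Carlo placement oracle
        assert p0(TheoryParams(go_angle=math.pi / 2)) == pytest.approx(
            0.2122210533, abs=1e-9
        )

    def test_dense_limit_is_arc_fraction(self):
        tp = TheoryParams(density=1600.0, go_angle=math.pi / 2)  # N = 1e6
        assert abs(p0(tp) - 0.25) < 1e-9

    def test_dilute_limit_vanishes(self):
        tp = TheoryParams(density=0.0, go_angle=math.pi / 2)
        assert p0(tp) == pytest.approx(0.0, abs=1e-12)

    def test_potential_variant_dense_limit_is_one(self):
        tp = TheoryParams(density=1600.0, go_angle=0.1)
        assert p0_potential(tp) == pytest.approx(1.0, abs=1e-9)

    def test_potential_variant_zero_arc(self):
        assert p0_potential(TheoryParams(go_angle=0.0)) == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.floats(0.05, 3.0),
        st.floats(0.0, 2.0 * math.pi),
    )
    def test_potential_variant_never_below_q_variant(self, density, go_angle):
        tp = TheoryParams(density=density, go_angle=go_angle)
        assert p0_potential(tp) >= p0(tp) - 1e-12


class TestCumulativeProbability:
    def test_first_epoch_is_p0(self):
        tp = TheoryParams(go_angle=math.pi / 2)
        t = np.array([0.0, 0.5, 0.999])
        np.testing.assert_allclose(p_of_t(tp, t), p0(tp))

    def test_certain_success_saturates(self):
        tp = TheoryParams(density=1600.0, go_angle=2 * math.pi)
        assert np.all(p_of_t(tp, np.arange(5.0)) == pytest.approx(1.0, abs=1e-9))

    def test_independent_epoch_product(self):
        tp = TheoryParams(go_angle=math.pi / 2)
        pz = p0(tp)
        # enumeration oracle: one independent chance per epoch incl. t=0
        expected = 1.0 - (1.0 - pz) ** 6
        assert p_of_t(tp, np.array([5.0]))[0] == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 3.0), st.floats(0.0, 2 * math.pi))
    def test_monotone_and_bounded(self, density, go_angle):
        tp = TheoryParams(density=density, go_angle=go_angle)
        p = p_of_t(tp, np.linspace(0.0, 50.0, 200))
        assert np.all(p >= -1e-12) and np.all(p <= 1.0 + 1e-12)
        assert np.all(np.diff(p) >= -1e-12)


class TestDriftMSD:
    def test_permanent_attachment_is_ballistic(self):
        tp = TheoryParams(density=1600.0, go_angle=2 * math.pi)
        t = np.linspace(0.0, 20.0, 50)
        short, long_ = msd_theory(tp, t)
        np.testing.assert_allclose(short, (tp.speed * t) ** 2, rtol=1e-9)
        np.testing.assert_allclose(long_, (tp.speed * t) ** 2, rtol=1e-9)

    def test_constant_probability_limit(self):
        # huge perception time: p stays at p0 on the whole grid
        tp = TheoryParams(go_angle=math.pi / 2, perception_time=1e6)
        t = np.linspace(0.0, 100.0, 20)
        short, _ = msd_theory(tp, t)
        np.testing.assert_allclose(short, (p0(tp) * tp.speed * t) ** 2, rtol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.02, 2.0), st.floats(0.1, 2 * math.pi))
    def test_asymptotic_drift_at_least_p0_v0(self, density, go_angle):
        tp = TheoryParams(density=density, go_angle=go_angle)
        t = np.array([1000.0])
        _, long_ = msd_theory(tp, t)
        assert long_[0] >= (p0(tp) * tp.speed * t[0]) ** 2 * (1.0 - 1e-9)


class TestFits:
    def test_phi0_slope_exact_recovery(self):
        om = np.array([-1.0, -0.5, 0.5, 1.0])
        assert fit_phi0_slope(om, -0.64 * om) == pytest.approx(-0.64)

    def test_phi0_slope_zero_data(self):
        om = np.array([-1.0, 1.0])
        assert fit_phi0_slope(om, np.zeros(2)) == 0.0

    def test_phi0_slope_unbiased_under_noise(self):
        rng = np.random.default_rng(17)
        om = np.linspace(-1.2, 1.2, 7)
        sxx = (om**2).sum()
        slope_sd = 0.02 / math.sqrt(sxx)
        slopes = [
            fit_phi0_slope(om, -0.64 * om + 0.02 * rng.standard_normal(7))
            for _ in range(100)
        ]
        assert abs(np.mean(slopes) + 0.64) < 3.0 * slope_sd / math.sqrt(100)

    def test_phi0_slope_needs_two_frequencies(self):
        with pytest.raises(ValueError):
            fit_phi0_slope(np.array([0.3]), np.array([0.1]))

    def test_dphi_fit_exact_recovery(self):
        dr = np.array([0.05, 0.1, 0.3, 0.6, 1.0])
        a, b, c = 1.0, 10.0, 0.001
        dphi = a + b * dr + c / dr
        coef = fit_dphi_vs_dr(dr, dphi)
        assert coef == pytest.approx((a, b, c), abs=1e-8)

    def test_dphi_fit_without_divergent_term(self):
        dr = np.array([0.05, 0.1, 0.3, 0.6, 1.0])
        _, _, c = fit_dphi_vs_dr(dr, 0.5 + 2.0 * dr)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_dphi_fit_degenerate_designs(self):
        with pytest.raises(ValueError):
            fit_dphi_vs_dr(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_dphi_vs_dr(np.array([-0.1, 0.2, 0.3]), np.ones(3))

    def test_loglog_slope_of_power_laws(self):
        t = np.linspace(0.5, 50.0, 200)
        from ihp.analysis import MSDCurve

        quad = MSDCurve(t, (1.5 * t) ** 2, np.zeros_like(t), 1)
        lin = MSDCurve(t, 4.0 * t, np.zeros_like(t), 1)
        assert loglog_slope(quad, (1.0, 40.0)) == pytest.approx(2.0, abs=1e-9)
        assert loglog_slope(lin, (1.0, 40.0)) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            loglog_slope(quad, (60.0, 70.0))


class TestAgainstSimulation:
    """Drift theory against the package's own trained-agent ensemble."""

    def test_short_time_drift_is_a_lower_bound(self, q_ensemble, trained_low_dr):
        """Within the first epoch the squared integrated drift (p0 v0 t)^2
        under-counts the Bernoulli attachment fluctuations and the initial
        attachment jump, so it must lie below the simulated MSD."""
        tp = TheoryParams(go_angle=trained_low_dr.diagram.go_angle)
        curve = ensemble_msd(q_ensemble)
        sel = (curve.times > 0) & (curve.times <= 1.0)
        short, _ = msd_theory(tp, curve.times[sel])
        assert np.all(short <= curve.msd[sel] + 3.0 * curve.stderr[sel])

    def test_long_time_drift_is_an_upper_bound(self, q_ensemble, trained_low_dr):
        """The asymptotic drift speed ignores the directional spread across
        the GO arc and occasional partner searches, so its ballistic curve
        bounds the simulated MSD from above but stays within a factor ~4."""
        bath_tau = 1.0 / (6.0e-3 * math.pi**2)
        tp = TheoryParams(go_angle=trained_low_dr.diagram.go_angle)
        curve = ensemble_msd(q_ensemble)
        sel = curve.times >= 30.0 * bath_tau
        _, long_ = msd_theory(tp, curve.times[sel])
        assert np.all(curve.msd[sel] <= long_ + 3.0 * curve.stderr[sel])
        assert np.all(long_ <= 4.0 * curve.msd[sel])

    def test_attachment_fraction_matches_p0_at_start(self, q_ensemble, trained_low_dr):
        tp = TheoryParams(go_angle=trained_low_dr.diagram.go_angle)
        _, frac = attachment_fraction(q_ensemble)
        se = math.sqrt(0.25 / len(q_ensemble))
        assert abs(frac[0] - p0(tp)) < 3.0 * se
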