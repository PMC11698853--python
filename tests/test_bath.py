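"""Bath generator and propagator: exact deterministic limits, periodic
geometry, and agreement with closed-form statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihp import (
    BathParams,
    BathState,
    abp_msd_closed_form,
    init_bath,
    make_fixture,
    minimum_image,
    nearest_particle,
    step_bath,
)
from ihp.bath import simulate_free_abp

TWO_PI = 2.0 * math.pi


def _circumcentre(a, b, c):
    """Centre of the circle through three points."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    return np.array([ux, uy])


class TestInit:
    def test_empty_bath_is_valid(self):
        state = init_bath(BathParams.from_count(0), np.random.default_rng(0))
        assert state.n_particles == 0
        assert state.time == 0.0

    def test_positions_and_angles_in_range(self):
        params = BathParams()  # rho=0.6, L=25 -> N=375
        assert params.n_particles == 375
        state = init_bath(params, np.random.default_rng(1))
        assert state.positions.shape == (375, 2)
        assert np.all((state.positions >= 0) & (state.positions < 25.0))
        assert np.all((state.angles >= 0) & (state.angles < TWO_PI))

    def test_same_seed_bitwise_identical(self):
        params = BathParams()
        a = init_bath(params, np.random.default_rng(7))
        b = init_bath(params, np.random.default_rng(7))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.angles, b.angles)


class TestStep:
    def test_noiseless_straight_motion(self):
        params = BathParams.from_count(1, rot_diffusivity=0.0)
        state = BathState(np.array([[5.0, 5.0]]), np.array([0.0]))
        new = step_bath(state, params, np.random.default_rng(0))
        assert new.positions[0] == pytest.approx([5.25, 5.0], abs=1e-12)
        assert new.time == pytest.approx(params.dt)

    def test_deterministic_rotation(self):
        omega = 0.6
        params = BathParams.from_count(1, rot_diffusivity=0.0, circ_frequency=omega)
        state = BathState(np.array([[5.0, 5.0]]), np.array([1.0]))
        rng = np.random.default_rng(0)
        for n in range(1, 30):
            state = step_bath(state, params, rng)
            assert state.angles[0] == pytest.approx((1.0 + omega * n * params.dt) % TWO_PI)

    def test_speed_is_exactly_v0_every_step(self):
        params = BathParams(box_length=10.0, density=0.5)
        rng = np.random.default_rng(3)
        state = init_bath(params, rng)
        for _ in range(5):
            new = step_bath(state, params, rng)
            delta = minimum_image(new.positions - state.positions, params.box_length)
            speeds = np.hypot(delta[:, 0], delta[:, 1]) / params.dt
            np.testing.assert_allclose(speeds, params.speed, rtol=1e-12)
            state = new

    def test_orientational_variance_grows_as_2_dr_t(self):
        # free Brownian rotation: Var[phi(t)] = 2 D_r t exactly at step level
        dr, t = 0.1, 10.0
        params = BathParams.from_count(0, rot_diffusivity=dr)
        n, steps = 100_000, round(t / params.dt)
        rng = np.random.default_rng(11)
        phi = np.zeros(n)
        for _ in range(steps):
            phi += params.noise_amplitude * rng.standard_normal(n)
        var = phi.var(ddof=1)
        se = var * math.sqrt(2.0 / (n - 1))
        assert abs(var - 2.0 * dr * t) < 3.0 * se

    def test_circling_fixture_closes_circle(self):
        fx = make_fixture("circling-abp")
        params = fx.params
        omega = params.circ_frequency
        state = fx.to_state()
        rng = np.random.default_rng(0)
        start = state.positions[0].copy()
        radius = params.speed / abs(omega)
        steps = round(TWO_PI / (abs(omega) * params.dt))
        pts = []
        for _ in range(steps):
            state = step_bath(state, params, rng, noise_scale=fx.noise_scale())
            pts.append(state.positions[0].copy())
        pts = np.array(pts)
        # polygonal orbit: every vertex lies on one circle whose radius is
        # v0/|omega| up to O(dt^2) discretisation
        centre = _circumcentre(pts[0], pts[20], pts[40])
        dist = np.hypot(*(pts - centre).T)
        assert dist.std() < 1e-9
        assert dist.mean() == pytest.approx(radius, rel=2e-3)
        assert np.hypot(*(state.positions[0] - start)) < params.speed * params.dt


class TestClosedFormMSD:
    def test_short_time_ballistic_limit(self):
        params = BathParams()
        t = np.array([1e-6])
        assert abp_msd_closed_form(t, params)[0] / t[0] ** 2 == pytest.approx(
            params.speed**2, rel=1e-4
        )

    def test_long_time_diffusive_limit(self):
        params = BathParams()
        t = np.array([1e7])
        expected = 2.0 * params.speed**2 / params.rot_diffusivity
        assert abp_msd_closed_form(t, params)[0] / t[0] == pytest.approx(expected, rel=1e-4)

    def test_rejects_chiral_and_nondiffusive(self):
        with pytest.raises(ValueError):
            abp_msd_closed_form(np.array([1.0]), BathParams(circ_frequency=0.1))
        with pytest.raises(ValueError):
            abp_msd_closed_form(np.array([1.0]), BathParams(rot_diffusivity=0.0))


class TestNearestParticle:
    def test_within_and_beyond_scan_radius(self):
        st_ = BathState(np.array([[5.5, 5.0]]), np.array([0.0]))
        assert nearest_particle([5.0, 5.0], st_, 1.0, 25.0) == 0
        st_far = BathState(np.array([[6.2, 5.0]]), np.array([0.0]))
        assert nearest_particle([5.0, 5.0], st_far, 1.0, 25.0) is None

    def test_minimum_image_across_seam(self):
        st_ = BathState(np.array([[24.9, 0.0]]), np.array([0.0]))
        assert nearest_particle([0.1, 0.0], st_, 1.0, 25.0) == 0
        delta = minimum_image(np.array([24.9 - 0.1]), 25.0)
        assert delta[0] == pytest.approx(-0.2)

    def test_empty_bath_returns_none(self):
        st_ = BathState(np.empty((0, 2)), np.empty(0))
        assert nearest_particle([0.0, 0.0], st_, 1.0, 25.0) is None


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(-50.0, 50.0))
def test_minimum_image_stays_in_half_box(delta):
    box = 25.0
    d = float(minimum_image(np.array([delta]), box)[0])
    assert -box / 2 <= d <= box / 2
    # same point modulo the box
    assert (d - delta) % box == pytest.approx(0.0, abs=1e-9) or (
        (d - delta) % box == pytest.approx(box, abs=1e-9)
    )


def test_free_abp_times_must_align_with_grid():
    with pytest.raises(ValueError):
        simulate_free_abp(BathParams(), 10, [0.1], np.random.default_rng(0))
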