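"""Stimulus generator: geometry, speed/size laws, and dot dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egoflow import flowfield as ff


class TestGeometry:
    def test_wide_field_extents(self, geometry):
        """20-cm viewing distance with +/-34.5 deg / +/-27.5 deg
        half-extents gives the full 69/55/82-deg field (nearest deg)."""
        assert round(2 * geometry.h_half_deg) == 69
        assert round(2 * geometry.v_half_deg) == 55
        assert round(2 * geometry.oblique_half_deg) == 82

    def test_square_screen_oblique_closed_form(self):
        d = 50.0
        side = d * math.tan(math.radians(45.0))
        g = ff.make_field_geometry(d, side, side)
        assert g.oblique_half_deg == pytest.approx(math.degrees(math.atan(math.sqrt(2))), abs=1e-9)

    def test_half_angle_vs_ray_projection_oracle(self):
        """atan(w/d) checked against a brute-force ray-projection oracle
        that samples screen points and takes the max subtended angle."""
        g = ff.make_field_geometry(57.3, 10.0, 10.0)
        assert g.h_half_deg == pytest.approx(9.899, abs=1e-3)
        # oracle: angles of densely sampled screen offsets
        offsets = np.linspace(0, 10.0, 10001)
        oracle = np.degrees(np.arctan2(offsets, 57.3)).max()
        assert g.h_half_deg == pytest.approx(oracle, abs=1e-9)

    @given(st.floats(0.1, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_deg_cm_roundtrip(self, angle):
        g = ff.make_field_geometry(20.0, 15.0, 12.0)
        assert g.cm_to_deg(g.deg_to_cm(angle)) == pytest.approx(angle, abs=1e-9)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_invalid_geometry_rejected(self, args):
        with pytest.raises(ff.GeometryError):
            ff.make_field_geometry(*args)

    def test_corner_eccentricity_within_oblique_extent(self, geometry):
        ecc = geometry.eccentricity(geometry.h_half_deg, geometry.v_half_deg)
        assert ecc == pytest.approx(geometry.oblique_half_deg, abs=1e-9)


class TestSpeedLaw:
    def test_endpoints_all_profiles(self, geometry):
        import warnings

        for p in ff.SPEED_PROFILES.values():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # mid tier: infeasible mean
                assert ff.dot_speed(0.0, p, geometry) == pytest.approx(p.v_min)
                assert ff.dot_speed(
                    geometry.max_eccentricity_deg, p, geometry
                ) == pytest.approx(p.v_max)

    def test_mid_profile_mean_clamps_to_linear_limit(self):
        """The mid tier's printed 30 deg/s mean lies just below the
        concave-log law's infimum on this field; calibration warns and
        settles at the quasi-linear law (closest achievable mean)."""
        g = ff.default_geometry()
        p = ff.SpeedProfile(5.0, 50.0, 30.0)
        with pytest.warns(UserWarning, match="unattainable"):
            p.calibrated_scale(g)
        x = np.linspace(-g.h_half_deg, g.h_half_deg, 201)
        y = np.linspace(-g.v_half_deg, g.v_half_deg, 201)
        xx, yy = np.meshgrid(x, y)
        mean = ff.dot_speed(g.eccentricity(xx, yy).ravel(), p, g).mean()
        assert mean == pytest.approx(31.0, abs=0.5)

    def test_monotone_nondecreasing(self, geometry, low_profile):
        e = np.linspace(0, geometry.max_eccentricity_deg, 500)
        v = ff.dot_speed(e, low_profile, geometry)
        assert np.all(np.diff(v) >= 0)

    @pytest.mark.parametrize("tier", ["low", "high"])
    def test_calibrated_mean_speed_monte_carlo(self, geometry, tier, rng):
        """Number-weighted mean over 1e5 uniformly placed dots hits the
        target mean speed (Monte-Carlo integration oracle)."""
        p = ff.SPEED_PROFILES[tier]
        x = rng.uniform(-geometry.h_half_deg, geometry.h_half_deg, 100_000)
        y = rng.uniform(-geometry.v_half_deg, geometry.v_half_deg, 100_000)
        mean = ff.dot_speed(geometry.eccentricity(x, y), p, geometry).mean()
        assert mean == pytest.approx(p.v_mean_target, abs=0.5 * p.v_mean_target / 18)

    def test_out_of_field_eccentricity_rejected(self, geometry, low_profile):
        with pytest.raises(ff.OutOfFieldError):
            ff.dot_speed(geometry.max_eccentricity_deg + 1.0, low_profile, geometry)


class TestDotSize:
    def test_affine_endpoints_and_midpoint(self, geometry):
        e_max = geometry.max_eccentricity_deg
        assert ff.dot_size(0.0, geometry) == pytest.approx(0.1)
        assert ff.dot_size(e_max, geometry) == pytest.approx(4.0)
        assert ff.dot_size(e_max / 2, geometry) == pytest.approx(2.05)

    def test_out_of_field_rejected(self, geometry):
        with pytest.raises(ff.OutOfFieldError):
            ff.dot_size(90.0, geometry)


class TestVelocityField:
    def test_translational_horizontal(self, geometry, low_profile):
        v = ff.velocity_field(np.array([5.0, 7.0]), "translational", 1, low_profile, geometry)
        s = ff.dot_speed(geometry.eccentricity(5.0, 7.0), low_profile, geometry)
        assert v == pytest.approx([s, 0.0])

    def test_circular_orthogonal_to_radius(self, geometry, low_profile, rng):
        pos = rng.uniform(-20, 20, size=(200, 2))
        v = ff.velocity_field(pos, "circular", 1, low_profile, geometry)
        assert np.abs((v * pos).sum(axis=1)).max() < 1e-9

    def test_radial_sign_flip_oracle(self, geometry, low_profile, rng):
        pos = rng.uniform(-20, 20, size=(1000, 2))
        out = ff.velocity_field(pos, "radial", +1, low_profile, geometry)
        inward = ff.velocity_field(pos, "radial", -1, low_profile, geometry)
        np.testing.assert_allclose(out, -inward, atol=1e-12)

    def test_speed_magnitude_matches_law(self, geometry, low_profile, rng):
        pos = rng.uniform(-15, 15, size=(100, 2))
        for cond in ff.COHERENT_CONDITIONS:
            v = ff.velocity_field(pos, cond, 1, low_profile, geometry)
            expected = ff.dot_speed(
                geometry.eccentricity(pos[:, 0], pos[:, 1]), low_profile, geometry
            )
            np.testing.assert_allclose(np.hypot(v[:, 0], v[:, 1]), expected, rtol=1e-9)

    def test_center_is_zero_for_rotational_flows(self, geometry, low_profile):
        for cond in ("circular", "radial", "spiral"):
            v = ff.velocity_field(np.array([0.0, 0.0]), cond, 1, low_profile, geometry)
            assert np.allclose(v, 0.0)

    def test_random_condition_unsupported(self, geometry, low_profile):
        with pytest.raises(ff.UnsupportedConditionError):
            ff.velocity_field(np.array([1.0, 1.0]), "random", 1, low_profile, geometry)


class TestStepFlow:
    def test_reversal_negates_velocities(self, geometry, low_profile):
        """Stepping across t = 0.5 s flips every coherent velocity."""
        state = ff.init_field("translational", geometry, low_profile, seed=3)
        rng = np.random.default_rng(99)
        dt = 1 / 60
        while state.sim_time + dt < 0.5 - 1e-9:
            state = ff.step_flow(state, dt, rng)
        before = np.sign(state.velocities[:, 0])
        state = ff.step_flow(state, dt, rng)  # crosses 0.5 s
        after = np.sign(state.velocities[:, 0])
        assert np.all(before == -after)

    def test_lifetime_respawn(self, geometry, low_profile):
        state = ff.init_field("translational", geometry, low_profile, seed=4)
        rng = np.random.default_rng(5)
        dt = 1 / 60
        max_age = 0.0
        for _ in range(60):
            state = ff.step_flow(state, dt, rng)
            max_age = max(max_age, state.ages.max())
        assert max_age <= ff.DOT_LIFETIME_S + 1e-12
        assert state.ages.min() < 0.35  # respawns occurred

    def test_static_positions_bit_identical(self, geometry, low_profile):
        state = ff.init_field("static", geometry, low_profile, seed=6)
        initial = state.positions.copy()
        rng = np.random.default_rng(7)
        for _ in range(100):
            state = ff.step_flow(state, 1 / 60, rng)
        assert np.array_equal(state.positions, initial)
        assert np.all(state.velocities == 0.0)

    def test_negative_dt_rejected(self, geometry, low_profile):
        state = ff.init_field("radial", geometry, low_profile, seed=1)
        with pytest.raises(ValueError):
            ff.step_flow(state, -0.01, np.random.default_rng(0))

    def test_circular_conserves_eccentricity(self, geometry, low_profile):
        """A circular-flow dot stays on its circle (exact rotation)."""
        state = ff.init_field("circular", geometry, low_profile, seed=8)
        rng = np.random.default_rng(9)
        r0 = np.hypot(state.positions[:, 0], state.positions[:, 1])
        ages0 = state.ages.copy()
        state2 = ff.step_flow(state, 1 / 60, rng)
        survived = state2.ages > ages0  # not respawned
        r1 = np.hypot(state2.positions[:, 0], state2.positions[:, 1])
        drift = np.abs(r1[survived] - r0[survived]) / np.maximum(r0[survived], 1e-9)
        assert drift.max() < 0.005 * 0.35 / (1 / 60)  # far under 0.5% per lifetime

    def test_translational_constant_speed_and_size_over_lifetime(
        self, geometry, low_profile
    ):
        state = ff.init_field("translational", geometry, low_profile, seed=10)
        rng = np.random.default_rng(11)
        speeds0 = np.hypot(state.velocities[:, 0], state.velocities[:, 1])
        sizes0 = state.sizes.copy()
        ages0 = state.ages.copy()
        state2 = ff.step_flow(state, 1 / 60, rng)
        survived = state2.ages > ages0
        speeds1 = np.hypot(state2.velocities[:, 0], state2.velocities[:, 1])
        np.testing.assert_allclose(speeds1[survived], speeds0[survived], rtol=1e-12)
        np.testing.assert_array_equal(state2.sizes[survived], sizes0[survived])

    def test_same_seed_bit_identical_different_seed_differs(self, geometry, low_profile):
        a = ff.simulate_clip("radial", 1.0, seed=21, geometry=geometry, profile=low_profile)
        b = ff.simulate_clip("radial", 1.0, seed=21, geometry=geometry, profile=low_profile)
        c = ff.simulate_clip("radial", 1.0, seed=22, geometry=geometry, profile=low_profile)
        assert np.array_equal(a[-1].positions, b[-1].positions)
        assert not np.array_equal(a[-1].positions, c[-1].positions)


class TestSummaries:
    def test_three_second_clip_statistics(self, geometry, low_profile):
        frames = ff.simulate_clip("translational", 3.0, seed=17)
        s = ff.summarize_stimulus(frames)
        assert s["mean_density"] == pytest.approx(0.04, rel=0.10)
        assert s["max_age"] <= 0.350 + 1e-12
        assert s["reversal_times"] == pytest.approx([0.5, 1.0, 1.5, 2.0, 2.5], abs=1e-6)

    def test_random_condition_density_and_speed_bounds(self, geometry, low_profile):
        frames = ff.simulate_clip("random", 2.0, seed=13)
        s = ff.summarize_stimulus(frames)
        assert s["mean_density"] == pytest.approx(0.04, rel=0.10)
        speeds = np.hypot(frames[-1].velocities[:, 0], frames[-1].velocities[:, 1])
        assert speeds.min() >= ff.SPEED_PROFILES["low"].v_min - 1e-9
        assert speeds.max() <= ff.SPEED_PROFILES["low"].v_max + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ff.summarize_stimulus([])

    def test_frame_table_columns(self, geometry, low_profile):
        frames = ff.simulate_clip("spiral", 0.2, seed=2)
        table = ff.frames_to_table(frames)
        assert list(table.columns) == ["t", "x_deg", "y_deg", "vx", "vy", "size_deg", "age"]
        assert len(table) == sum(f.n_dots for f in frames)
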