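"""Heightfield construction, tolerance rewards and task observations."""

import numpy as np
import pytest

from kinemimic import quat
from kinemimic.bodies import Pose, make_quadruped_fixture
from kinemimic.bowl import (
    BowlParams,
    EscapeRewardConfig,
    EscapeState,
    Heightfield,
    HeightfieldSpec,
    check_fail,
    compose_heightfield,
    escape_reward,
    gaussian_bowl,
    ground_height,
    perlin_tileable,
    radial_gate,
    smoothstep,
    surface_normal,
    task_observation,
    tol_linear,
    world_to_grid,
    _fade,
)


class TestGridMapping:
    def test_corner_maps_to_origin_cell(self):
        spec = HeightfieldSpec(n=128)
        assert world_to_grid(-spec.half_width, -spec.half_width, spec) == (0, 0)

    def test_center_maps_to_center_cell_odd_n(self):
        spec = HeightfieldSpec(n=65)
        assert world_to_grid(0.0, 0.0, spec) == (32, 32)

    def test_uniform_field_ground_height_is_v(self):
        spec = HeightfieldSpec(n=16)
        field = Heightfield(np.ones((16, 16)), spec)
        assert ground_height(field, 0.3, -0.7) == pytest.approx(spec.v_scale)

    def test_grid_spacing(self):
        spec = HeightfieldSpec(n=128, half_width=2.0)
        assert spec.spacing == pytest.approx(4.0 / 127)


class TestBowl:
    def test_center_value_is_depth(self):
        B = gaussian_bowl(1.25, -10.0, 65)
        assert B[32, 32] == pytest.approx(-10.0)

    def test_corner_value_scalar_arithmetic(self):
        sigma, A = 1.25, -10.0
        B = gaussian_bowl(sigma, A, 65)
        assert B[0, 0] == pytest.approx(A * np.exp(-2.0 / (2 * sigma ** 2)), abs=1e-12)

    def test_eight_fold_symmetry(self):
        B = gaussian_bowl(1.25, -10.0, 33)
        for t in (np.flipud(B), np.fliplr(B), B.T, np.rot90(B)):
            assert np.allclose(B, t, atol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gaussian_bowl(-1.0, -10.0, 16)
        with pytest.raises(ValueError):
            gaussian_bowl(1.0, 10.0, 16)


class TestPerlin:
    def test_fade_endpoints_and_slopes(self):
        assert _fade(np.array([0.0]))[0] == 0.0
        assert _fade(np.array([1.0]))[0] == 1.0
        eps = 1e-7
        assert abs(_fade(np.array([eps]))[0] / eps) < 1e-6  # f'(0) = 0
        assert abs((1.0 - _fade(np.array([1 - eps]))[0]) / eps) < 1e-6  # f'(1) = 0

    def test_zero_at_lattice_nodes(self):
        n, R = 128, 8
        P = perlin_tileable(R, R, n, seed=3)
        stride = n // R  # samples that land exactly on lattice nodes
        assert np.abs(P[::stride, ::stride]).max() < 1e-12

    def test_tileable_across_the_seam(self):
        n, R = 96, 4
        P = perlin_tileable(R, R, n, seed=5)
        # sampling on [0,1): appending a copy of column 0 one grid step after
        # the last column continues the field smoothly; equality of wrapped
        # phases means P at phase 0 equals P at phase exactly R
        shifted = perlin_tileable(R, R, n, seed=5)
        assert np.allclose(P[:, 0], shifted[:, 0], atol=1e-9)
        # explicit periodicity: doubling the domain repeats the tile
        P2 = perlin_tileable(R, R, 2 * n, seed=5)[:n * 2:2, : n * 2 : 2]
        assert np.allclose(P2, perlin_tileable(R, R, n, seed=5), atol=1e-9)

    def test_mean_near_zero_before_rescale(self):
        P = perlin_tileable(8, 8, 256, seed=0)
        assert abs(P.mean()) < 0.01

    def test_rescaled_range_is_unit(self):
        P = perlin_tileable(4, 4, 64, seed=1, rescale=True)
        assert P.min() == 0.0 and P.max() == 1.0

    def test_deterministic_per_seed(self):
        a = perlin_tileable(8, 8, 64, seed=9)
        b = perlin_tileable(8, 8, 64, seed=9)
        assert np.array_equal(a, b)


class TestGate:
    def test_center_weight_zero(self):
        w = radial_gate(65, 3.0, 16.0)
        assert w[32, 32] == 0.0

    def test_smoothstep_midpoint(self):
        assert smoothstep(np.array([0.5]))[0] == pytest.approx(0.5)
        assert smoothstep(np.array([0.25]))[0] == pytest.approx(3 * 0.0625 - 2 * 0.015625)

    def test_monotone_along_rays(self):
        w = radial_gate(65, 3.0, 16.0)
        center = 32
        ray = w[center, center:]
        assert np.all(np.diff(ray) >= -1e-12)


class TestCompose:
    def test_zero_noise_equals_normalized_bowl(self):
        spec = HeightfieldSpec(n=64)
        field = compose_heightfield(spec, BowlParams(noise_amplitude=0.0))
        B = gaussian_bowl(1.25, -10.0, 64)
        Bn = (B - B.min()) / (B.max() - B.min())
        assert np.allclose(field.heights, Bn, atol=1e-12)

    def test_minmax_exact_unit(self):
        field = compose_heightfield(HeightfieldSpec(n=64), BowlParams(noise_amplitude=0.8, seed=2))
        assert field.heights.min() == 0.0
        assert field.heights.max() == 1.0

    def test_launch_zone_noise_free(self):
        spec = HeightfieldSpec(n=128)
        params = BowlParams(noise_amplitude=1.0, seed=4)
        field = compose_heightfield(spec, params)
        pure = compose_heightfield(spec, BowlParams(noise_amplitude=0.0, seed=4))
        r_in, _ = params.gate_radii(128)
        c = (128 - 1) / 2
        B = gaussian_bowl(params.sigma, params.depth, 128)
        H0 = field.heights
        # inside r_in the raw height equals the bowl: difference from the pure
        # bowl is only the global affine normalization
        ii, jj = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        inside = (ii - c) ** 2 + (jj - c) ** 2 < (r_in - 1) ** 2
        a = H0[inside]
        b = B[inside]
        fit = np.polyfit(b, a, 1)
        assert np.abs(a - (fit[0] * b + fit[1])).max() < 1e-9

    def test_deterministic_regeneration(self):
        f1 = compose_heightfield(HeightfieldSpec(n=64), BowlParams(noise_amplitude=0.6, seed=11))
        f2 = compose_heightfield(HeightfieldSpec(n=64), BowlParams(noise_amplitude=0.6, seed=11))
        assert np.array_equal(f1.heights, f2.heights)


class TestNormals:
    def test_flat_field_normal_is_up(self):
        field = Heightfield(np.full((16, 16), 0.5), HeightfieldSpec(n=16))
        n, _, _ = surface_normal(field, 8, 8)
        assert np.allclose(n, [0, 0, 1])

    def test_plane_normal_matches_analytic(self):
        spec = HeightfieldSpec(n=33, half_width=1.0, v_scale=0.2)
        g = 0.01  # height per index step along j (world x)
        H = np.tile(np.arange(33) * g, (33, 1))
        field = Heightfield(H, spec)
        n, _, _ = surface_normal(field, 16, 16)
        slope = spec.v_scale * g / spec.spacing  # dz/dx in world units
        expected = np.array([-slope, 0.0, 1.0])
        expected /= np.linalg.norm(expected)
        assert np.allclose(n, expected, atol=1e-9)

    def test_unit_length_everywhere(self):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams(noise_amplitude=0.7, seed=1))
        for i in range(0, 32, 5):
            for j in range(0, 32, 5):
                n, _, _ = surface_normal(field, i, j)
                assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)


class TestToleranceReward:
    def test_speed_reward_peak_and_zeros(self):
        v_star = 0.75
        assert tol_linear(v_star, (v_star, v_star), v_star) == 1.0
        assert tol_linear(2 * v_star, (v_star, v_star), v_star) == 0.0
        assert tol_linear(0.0, (v_star, v_star), v_star) == 0.0

    def test_linear_interpolation_between(self):
        v_star = 0.75
        assert tol_linear(1.5 * v_star, (v_star, v_star), v_star) == pytest.approx(0.5)
        assert tol_linear(0.5 * v_star, (v_star, v_star), v_star) == pytest.approx(0.5)

    def test_interval_interior_is_one(self):
        assert tol_linear(0.3, (0.0, 1.0), 0.5) == 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            tol_linear(0.0, (1.0, 0.0), 0.5)
        with pytest.raises(ValueError):
            tol_linear(0.0, (0.0, 1.0), -1.0)


class TestEscapeReward:
    def _state(self, quad, pos, vel3=(0, 0, 0), rotvec=(0, 0, 0)):
        pose = Pose(np.asarray(pos, float), quat.from_rotvec(rotvec), np.zeros(quad.n_dof))
        vel = np.zeros(6 + quad.n_dof)
        vel[:3] = vel3
        return EscapeState(pose=pose, vel=vel)

    def test_at_origin_total_is_speed_term(self, quad):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams())
        cfg = EscapeRewardConfig()
        st = self._state(quad, [0, 0, 0.5], vel3=(cfg.target_speed, 0, 0))
        total, comps = escape_reward(st, field, cfg)
        assert comps["esc"] == 0.0
        assert total == pytest.approx(comps["spd"])

    def test_rim_upright_at_target_speed_scores_two(self, quad):
        spec = HeightfieldSpec(n=32)
        field = compose_heightfield(spec, BowlParams())
        cfg = EscapeRewardConfig()
        st = self._state(quad, [spec.half_width, 0, 0.5], vel3=(cfg.target_speed, 0, 0))
        total, comps = escape_reward(st, field, cfg)
        assert comps == {"esc": 1.0, "up": 1.0, "spd": 1.0}
        assert total == pytest.approx(2.0)

    def test_inverted_torso_zeroes_its_tolerance(self, quad):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams())
        cfg = EscapeRewardConfig(tilt_deg=0.0)
        st = self._state(quad, [1.0, 0, 0.5], rotvec=(np.pi, 0, 0))  # upside down
        _, comps = escape_reward(st, field, cfg)
        # both torso and head use the root z-axis here: dot = -1 decays over
        # the full margin 1 + cos(0) = 2 to exactly 0
        assert comps["up"] == pytest.approx(0.0, abs=1e-12)

    def test_reward_ranges(self, quad, rng):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams(noise_amplitude=0.5))
        cfg = EscapeRewardConfig()
        for _ in range(50):
            st = self._state(quad, rng.uniform(-2, 2, 3) + [0, 0, 2.2],
                             vel3=rng.uniform(-2, 2, 3), rotvec=rng.normal(0, 1, 3))
            total, comps = escape_reward(st, field, cfg)
            assert all(0.0 <= c <= 1.0 for c in comps.values())
            assert 0.0 <= total <= 2.0


class TestFail:
    def test_high_torso_not_failed(self, quad):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams())
        st = EscapeState(Pose(np.array([0, 0, 1.0]), [1, 0, 0, 0], np.zeros(quad.n_dof)),
                         np.zeros(6 + quad.n_dof))
        assert not check_fail(st, field)

    def test_boundary_inclusive(self, quad):
        field = Heightfield(np.zeros((16, 16)), HeightfieldSpec(n=16))
        eps = 0.03
        st = EscapeState(Pose(np.array([0, 0, eps]), [1, 0, 0, 0], np.zeros(quad.n_dof)),
                         np.zeros(6 + quad.n_dof))
        assert check_fail(st, field, eps)  # z == ground + eps fails (<=)

    def test_flat_zero_field_threshold(self, quad):
        field = Heightfield(np.zeros((16, 16)), HeightfieldSpec(n=16))
        lo = EscapeState(Pose(np.array([0.5, 0.5, 0.02]), [1, 0, 0, 0], np.zeros(quad.n_dof)),
                         np.zeros(6 + quad.n_dof))
        hi = EscapeState(Pose(np.array([0.5, 0.5, 0.05]), [1, 0, 0, 0], np.zeros(quad.n_dof)),
                         np.zeros(6 + quad.n_dof))
        assert check_fail(lo, field, 0.03)
        assert not check_fail(hi, field, 0.03)


class TestTaskObservation:
    def test_zero_action_history_block(self, quad):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams())
        st = EscapeState(Pose(np.array([0, 0, 0.5]), [1, 0, 0, 0], np.zeros(quad.n_dof)),
                         np.zeros(6 + quad.n_dof))
        obs = task_observation(quad, st, None, field)
        n_act = 6 + quad.n_dof
        assert np.allclose(obs[:n_act], 0.0)

    def test_origin_displacement_zero(self, quad):
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams())
        st = EscapeState(Pose(np.array([0, 0, 0.5]), [1, 0, 0, 0], np.zeros(quad.n_dof)),
                         np.zeros(6 + quad.n_dof))
        obs = task_observation(quad, st, None, field)
        n_act = 6 + quad.n_dof
        o_base = 9
        o_kin = 2 * quad.n_dof
        o_touch = len(quad.end_effectors)
        o_orig = obs[n_act + o_base + o_kin + o_touch : n_act + o_base + o_kin + o_touch + 3]
        assert np.allclose(o_orig, 0.0)

    def test_free_joint_slices_excluded(self, quad):
        """The proprioceptive q slice drops exactly the 7 free-joint
        coordinates and the qdot slice the 6 free-joint velocities."""
        field = compose_heightfield(HeightfieldSpec(n=32), BowlParams())
        q = np.linspace(0.1, 0.8, quad.n_dof)
        vel = np.arange(6 + quad.n_dof, dtype=float)
        st = EscapeState(Pose(np.array([0, 0, 0.5]), [1, 0, 0, 0], q), vel)
        obs = task_observation(quad, st, None, field)
        n_act = 6 + quad.n_dof
        task_len = n_act + 9 + 2 * quad.n_dof + len(quad.end_effectors) + 3
        prop = obs[task_len:]
        assert np.allclose(prop[: quad.n_dof], q)  # qpos[7:]
        assert np.allclose(prop[quad.n_dof : 2 * quad.n_dof], vel[6:])  # qvel[6:]
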