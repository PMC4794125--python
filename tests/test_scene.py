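"""Geometry layer: super-quadrics, rigid transforms, needle poses, skins."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cfrwplan.scene import (AngleLimits, EllipticCylinderSkin, GriddedSkin,
                            NeedleGeometry, PolynomialSkin, RigidTransform,
                            SphereSkin, SuperQuadric, Target, Trajectory,
                            needle_transform, obstacle_transform, rot_y,
                            rot_z, skin_eval, skin_normal, sq_gradient,
                            sq_hessian, sq_value)

RNG = np.random.default_rng(42)


def random_pose(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return RigidTransform.from_quat(q, rng.uniform(-50, 50, 3))


def unit_sphere():
    return SuperQuadric((1.0, 1.0, 1.0), (2, 2, 2), 1.0)


class TestSuperQuadricValues:
    def test_canonical_value_at_origin_is_minus_level(self):
        head = NeedleGeometry.default().head_sq
        assert sq_value(head, np.zeros(3)) == pytest.approx(-1000.0)

    def test_on_surface_point_of_printed_head(self):
        # (ay'/0.1)^2 = 1000 at ay' = 0.1*sqrt(1000), other terms zero
        head = NeedleGeometry.default().head_sq
        p = np.array([0.0, 0.1 * np.sqrt(1000.0), 0.0])
        assert sq_value(head, p) == pytest.approx(0.0, abs=1e-9)

    def test_sign_agrees_with_independent_membership_oracle(self):
        """Posed ellipsoid signs vs an oracle using an inverse-matrix map."""
        rng = np.random.default_rng(7)
        pose = random_pose(rng)
        sq = SuperQuadric((5.0, 3.0, 2.0), (2, 2, 2), 1.0, pose)
        pts = rng.uniform(-15, 15, size=(1000, 3)) + pose.translation
        R = pose.rotation
        for p in pts:
            # independent evaluation: explicit matrix inverse, plain loops
            p_loc = np.linalg.inv(R) @ (p - pose.translation)
            val = sum((p_loc[i] / sq.scales[i]) ** 2 for i in range(3)) - 1.0
            if abs(val) > 1e-9:
                assert np.sign(sq_value(sq, p)) == np.sign(val)

    def test_value_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        sq = SuperQuadric((4.0, 2.0, 1.5), (4, 2, 6), 100.0, random_pose(rng))
        for _ in range(50):
            motion = random_pose(rng)
            moved = sq.posed(motion.compose(sq.pose))
            p = rng.uniform(-10, 10, 3)
            assert sq.value(p) == pytest.approx(moved.value(motion.apply(p)),
                                                abs=1e-10 * max(1, abs(sq.value(p))))

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            SuperQuadric((1, 1, 1), (3, 2, 2), 1.0)  # odd exponent
        with pytest.raises(ValueError):
            SuperQuadric((1, -1, 1), (2, 2, 2), 1.0)
        with pytest.raises(ValueError):
            sq_value(unit_sphere(), np.array([np.nan, 0, 0]))


class TestSuperQuadricDerivatives:
    def test_unit_sphere_gradient_and_hessian(self):
        sq = unit_sphere()
        assert np.allclose(sq_gradient(sq, [2.0, 0.0, 0.0]), [4.0, 0.0, 0.0])
        assert np.allclose(sq_hessian(sq, RNG.normal(size=3)), 2 * np.eye(3))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        sq = SuperQuadric((5.0, 2.0, 3.0), (8, 2, 4), 1000.0, random_pose(rng))
        eps = 1e-6
        for _ in range(100):
            p = sq.pose.translation + rng.uniform(-6, 6, 3)
            g = sq_gradient(sq, p)
            g_fd = np.array([
                (sq.value(p + eps * e) - sq.value(p - eps * e)) / (2 * eps)
                for e in np.eye(3)
            ])
            assert np.allclose(g, g_fd, rtol=1e-5, atol=1e-5 * np.abs(g).max())

    def test_hessian_matches_gradient_differences(self):
        rng = np.random.default_rng(5)
        sq = SuperQuadric((5.0, 2.0, 3.0), (8, 2, 4), 1000.0, random_pose(rng))
        eps = 1e-6
        for _ in range(50):
            p = sq.pose.translation + rng.uniform(-6, 6, 3)
            H = sq_hessian(sq, p)
            H_fd = np.column_stack([
                (sq.gradient(p + eps * e) - sq.gradient(p - eps * e)) / (2 * eps)
                for e in np.eye(3)
            ])
            scale = max(1.0, np.abs(H).max())
            assert np.allclose(H, H_fd, atol=1e-4 * scale)


class TestTransforms:
    def test_vertical_insertion_head_center(self, default_needle):
        l = default_needle.head_length
        traj = Trajectory(Target(np.array([1.0, 2.0, 3.0])),
                          np.array([1.0, 2.0, 103.0]))
        T = obstacle_transform(traj, default_needle)
        assert np.allclose(T.translation, [1.0, 2.0, 3.0 + l / 2])

    def test_head_center_matches_direct_substitution(self, default_needle):
        """45-degree insertion: o' from the closed-form spherical offset."""
        traj = Trajectory(Target(np.zeros(3)), np.array([1.0, 0.0, 1.0]))
        T = obstacle_transform(traj, default_needle)
        theta, phi = np.pi / 4, 0.0
        l = default_needle.head_length
        o_expect = np.array([l / 2 * np.sin(theta) * np.cos(phi),
                             l / 2 * np.sin(theta) * np.sin(phi),
                             l / 2 * np.cos(theta)])
        assert np.allclose(T.translation, o_expect, atol=1e-12)

    def test_local_axis_maps_parallel_to_needle_axis(self, default_needle):
        rng = np.random.default_rng(11)
        for _ in range(100):
            entry = rng.uniform(-80, 80, 3)
            entry[2] = rng.uniform(50, 150)
            tgt = Target(rng.uniform(-5, 5, 3))
            traj = Trajectory(tgt, entry)
            T = obstacle_transform(traj, default_needle)
            mapped_x = T.rotation @ np.array([1.0, 0.0, 0.0])
            cosang = abs(mapped_x @ traj.direction)
            assert cosang == pytest.approx(1.0, abs=1e-10)

    def test_needle_and_obstacle_transforms_agree(self, default_needle):
        rng = np.random.default_rng(13)
        for _ in range(100):
            theta = rng.uniform(0.05, 1.3)
            phi = rng.uniform(-np.pi, np.pi)
            tgt = Target(rng.uniform(-20, 20, 3))
            Tn = needle_transform((theta, phi), tgt, default_needle)
            traj = Trajectory.from_angles(tgt, theta, phi, length=180.0)
            To = obstacle_transform(traj, default_needle)
            assert np.allclose(Tn.rotation, To.rotation, atol=1e-10)
            assert np.allclose(Tn.translation, To.translation, atol=1e-9)
            R = Tn.rotation
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_vertical_needle_maps_origin_to_head_center(self, default_needle):
        tgt = Target(np.array([2.0, -1.0, 0.0]))
        T = needle_transform((0.0, 0.0), tgt, default_needle)
        expect = tgt.position + [0, 0, default_needle.head_length / 2]
        assert np.allclose(T.apply(np.zeros(3)), expect)

    def test_compose_inverse_roundtrip(self):
        rng = np.random.default_rng(17)
        A = random_pose(rng)
        B = random_pose(rng)
        p = rng.normal(size=3)
        assert np.allclose(A.compose(B).apply(p), A.apply(B.apply(p)))
        assert np.allclose(A.inverse().compose(A).apply(p), p, atol=1e-12)


class TestTargetsAndTrajectories:
    def test_compensated_position_identity(self):
        t = Target(np.array([1.0, 2.0, 3.0]), np.array([0.1, -0.2, 0.3]))
        assert np.allclose(t.compensated, [1.1, 1.8, 3.3])

    def test_angle_entry_roundtrip(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            theta = rng.uniform(0.01, 1.4)
            phi = rng.uniform(-np.pi, np.pi)
            traj = Trajectory.from_angles(Target(rng.normal(size=3)),
                                          theta, phi, length=120.0)
            assert traj.angles[0] == pytest.approx(theta, abs=1e-9)
            dphi = (traj.angles[1] - phi + np.pi) % (2 * np.pi) - np.pi
            assert dphi == pytest.approx(0.0, abs=1e-9)

    def test_zero_length_trajectory_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            Trajectory(Target(np.zeros(3)), np.zeros(3))

    def test_inconsistent_angles_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Trajectory(Target(np.zeros(3)), np.array([0.0, 0.0, 100.0]),
                       angles=(0.5, 0.0))


class TestSkins:
    def test_circular_cylinder_points_and_normals(self):
        skin = EllipticCylinderSkin(semi_x=100.0, semi_z=100.0,
                                    u_bounds=(-1.0, 1.0), v_bounds=(-50, 50))
        for u, v in [(-0.7, 0.0), (0.0, 10.0), (0.9, -20.0)]:
            p = skin_eval(skin, u, v)
            assert p[0] ** 2 + p[2] ** 2 == pytest.approx(100.0 ** 2)
            n = skin_normal(skin, u, v)
            radial = np.array([p[0], 0.0, p[2]])
            radial /= np.linalg.norm(radial)
            assert abs(n @ radial) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds_raises_with_bound_name(self):
        skin = SphereSkin(radius=50.0)
        with pytest.raises(ValueError, match="u="):
            skin_eval(skin, 10.0, 0.0)
        with pytest.raises(ValueError, match="v="):
            skin_normal(skin, 0.5, 100.0)

    def test_polynomial_plane_normal_is_vertical(self):
        skin = PolynomialSkin(coeffs=[[160.0]])
        assert np.allclose(skin_eval(skin, 3.0, -4.0), [3.0, -4.0, 160.0])
        assert np.allclose(skin_normal(skin, 3.0, -4.0), [0.0, 0.0, 1.0])

    def test_gridded_skin_reproduces_analytic_patch(self):
        analytic = EllipticCylinderSkin(semi_x=120.0, semi_z=150.0,
                                        u_bounds=(-0.6, 0.6),
                                        v_bounds=(-40.0, 40.0))
        grid = GriddedSkin.from_surface(analytic, nu=25, nv=25)
        # exact at the nodes
        for u in np.linspace(-0.6, 0.6, 25):
            assert np.allclose(grid.point(u, 0.0), analytic.point(u, 0.0),
                               atol=1e-9)
        # interpolation-order accurate between nodes
        rng = np.random.default_rng(23)
        for _ in range(50):
            u = rng.uniform(-0.6, 0.6)
            v = rng.uniform(-40, 40)
            assert np.allclose(grid.point(u, v), analytic.point(u, v),
                               atol=1e-4)
            assert np.allclose(grid.normal(u, v), analytic.normal(u, v),
                               atol=1e-4)


class TestAngleLimits:
    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            AngleLimits(1.0, 0.5, -1.0, 1.0)

    def test_full_circle_wraps_azimuth(self):
        lim = AngleLimits(0.0, 1.0, -np.pi, np.pi)
        assert lim.contains(0.5, 3 * np.pi)
        assert not lim.contains(1.5, 0.0)
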