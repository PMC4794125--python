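"""Boundary location, continuation tracing, and membership tests."""

import numpy as np
import pytest

from cfrwplan import cfrw, planner
from cfrwplan.cfrw import (CFRWBoundary, CFRWSystem, InfeasibleStartError,
                           LayerCurveSet, cfrw_for_needle, find_boundary_point,
                           point_parity, points_parity, trace_boundary,
                           trajectory_in_cfrw)
from cfrwplan.scene import AngleLimits, Target, Trajectory
from cfrwplan.synthetic_scenes import make_sphere_oracle_scene

from conftest import make_sphere_sq


def hausdorff(a, b):
    from scipy.spatial.distance import cdist
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestFindBoundaryPoint:
    def test_boundary_radius_matches_tangent_cone(self, sphere_setup,
                                                  sphere_boundary_state):
        _scene, oracle = sphere_setup
        rho = np.linalg.norm(sphere_boundary_state.u)
        # the barrier relaxation shifts the fold by ~mu/(2 gamma) of surface
        # clearance; stay within half a continuation step of the cone circle
        assert rho == pytest.approx(oracle.circle_radius(150.0), abs=0.25)

    def test_criterion_satisfied_at_boundary_point(self, sphere_system,
                                                   sphere_boundary_state):
        G, _M, scales = sphere_system.criterion_full(
            sphere_boundary_state.as_vector())
        assert np.max(np.abs(G) / scales) < 1e-8

    def test_opposite_directions_reach_distinct_points(self, sphere_system):
        a = find_boundary_point(sphere_system, np.array([80.0, 0.0]),
                                np.array([-1.0, 0.0]))
        b = find_boundary_point(sphere_system, np.array([80.0, 0.0]),
                                np.array([1.0, 0.0]))
        # inner boundary of the exclusion cone vs outer: distinct points of
        # one closed curve... the cone circle: marching inward hits the
        # circle from outside, marching outward exits through nothing, so
        # use two tangential directions instead
        assert np.linalg.norm(a.u - b.u) > 1.0

    def test_infeasible_start_raises(self, sphere_system):
        with pytest.raises(InfeasibleStartError):
            find_boundary_point(sphere_system, np.array([0.0, 0.0]),
                                np.array([1.0, 0.0]))

    def test_clearance_at_boundary_equals_gamma_with_mu_bias(
            self, sphere_setup, sphere_boundary_state):
        scene, _ = sphere_setup
        tgt = scene.targets[0]
        u = sphere_boundary_state.u
        entry = np.array([u[0] * 200.0 / 150.0, u[1] * 200.0 / 150.0, 200.0])
        d = planner.segment_surface_distance(tgt.compensated, entry,
                                             scene.obstacles[0])
        mu, gamma = 0.1, 1.5
        bias = mu / (2 * gamma)
        assert abs(d - gamma) < 10.0 * bias

    @pytest.mark.parametrize("mu", [0.1, 0.01, 0.001])
    def test_bias_shrinks_with_mu(self, sphere_setup, mu):
        scene, _oracle = sphere_setup
        system = CFRWSystem(scene.targets[0], scene.needle,
                            scene.obstacles[0], scene.angle_limits,
                            150.0, 1.5, mu)
        st = find_boundary_point(system, np.array([120.0, 0.0]),
                                 np.array([-1.0, 0.0]))
        entry = np.array([st.u[0] * 4 / 3, st.u[1] * 4 / 3, 200.0])
        d = planner.segment_surface_distance(scene.targets[0].compensated,
                                             entry, scene.obstacles[0])
        assert abs(d - 1.5) < 1.5 * mu / (2 * 1.5) + 5e-3


class TestTraceBoundary:
    def test_traced_circle_matches_cone_conic(self, sphere_setup,
                                              sphere_curve):
        _scene, oracle = sphere_setup
        assert sphere_curve.closed
        assert hausdorff(sphere_curve.points, oracle.circle(150.0, n=2048)) < 0.5

    def test_curve_is_closed(self, sphere_curve):
        gap = np.linalg.norm(sphere_curve.points[0] - sphere_curve.points[-1])
        assert gap < 0.5

    def test_stored_states_satisfy_criterion(self, sphere_system,
                                             sphere_curve):
        for st in sphere_curve.states[:: max(1, len(sphere_curve.states) // 20)]:
            G, _M, scales = sphere_system.criterion_full(st.as_vector())
            assert np.max(np.abs(G) / scales) < 1e-8
            assert np.linalg.norm(st.xi) == pytest.approx(1.0, abs=1e-8)

    def test_larger_gamma_shrinks_feasible_region(self, sphere_setup):
        """Monotonicity: the exclusion circle grows with gamma."""
        scene, _ = sphere_setup
        radii = []
        for gamma in (0.5, 1.5, 3.0):
            system = CFRWSystem(scene.targets[0], scene.needle,
                                scene.obstacles[0], scene.angle_limits,
                                150.0, gamma, 0.1)
            st = find_boundary_point(system, np.array([120.0, 0.0]),
                                     np.array([-1.0, 0.0]))
            radii.append(np.linalg.norm(st.u))
        assert radii[0] < radii[1] < radii[2]


class TestRayCasting:
    def test_unit_circle_membership(self):
        t = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([np.cos(t), np.sin(t)], axis=1)
        assert point_parity((0.0, 0.0), [circle]) == 1
        assert point_parity((2.0, 0.0), [circle]) == 0

    def test_annulus_hole_parity_matches_winding_oracle(self):
        t = np.linspace(0, 2 * np.pi, 300)
        outer = 2.0 * np.stack([np.cos(t), np.sin(t)], axis=1)
        inner = 1.0 * np.stack([np.cos(t), np.sin(t)], axis=1)
        rng = np.random.default_rng(2)
        pts = rng.uniform(-2.5, 2.5, size=(200, 2))

        def winding(p, curve):
            v = curve - p
            ang = np.arctan2(v[:, 1], v[:, 0])
            dang = np.diff(ang)
            dang = (dang + np.pi) % (2 * np.pi) - np.pi
            return int(round(abs(dang.sum()) / (2 * np.pi)))

        parity = points_parity(pts, [outer, inner])
        for p, par in zip(pts, parity):
            w = (winding(p, outer) + winding(p, inner)) % 2
            assert par == w

    def test_vertex_on_ray_retry_is_deterministic(self):
        square = np.array([[1.0, 0.0], [1.0, 1.0], [-1.0, 1.0],
                           [-1.0, -1.0], [1.0, -1.0], [1.0, 0.0]])
        # the query's +x ray passes exactly through the vertex (1, 0)
        assert point_parity((0.0, 0.0), [square]) == 1
        assert point_parity((3.0, 0.0), [square]) == 0

    def test_epsilon_offsets_flip_membership_across_curve(self, sphere_curve):
        pts = sphere_curve.points
        for k in range(0, len(pts) - 1, len(pts) // 10):
            p = pts[k]
            n = p / np.linalg.norm(p)  # circle normal is radial
            inside = point_parity(p - 1.0 * n, [pts])
            outside = point_parity(p + 1.0 * n, [pts])
            assert inside == 1 and outside == 0


class TestCFRWForNeedle:
    def test_no_obstacles_gives_free_membership(self, origin_target,
                                                default_needle, limits_full):
        bd = cfrw_for_needle(origin_target, default_needle, [], [150.0],
                             1.5, 0.1, limits_full)
        traj = Trajectory(origin_target, np.array([10.0, 0.0, 160.0]))
        assert trajectory_in_cfrw(traj, bd)

    def test_three_layers_give_three_stacked_curves(self, sphere_setup):
        scene, oracle = sphere_setup
        bd = cfrw_for_needle(scene.targets[0], scene.needle, scene.obstacles,
                             [150.0, 160.0, 170.0], 1.5, 0.1,
                             scene.angle_limits)
        assert len(bd.layers) == 3
        for ls in bd.layers:
            assert len(ls.curves) == 1
            radius = np.linalg.norm(ls.curves[0], axis=1).mean()
            assert radius == pytest.approx(oracle.circle_radius(ls.h),
                                           abs=0.35)

    def test_two_sphere_membership_equals_conjunction_of_cone_oracles(
            self, origin_target, limits_full):
        """Random trajectories against two disjoint spheres."""
        scene, _ = make_sphere_oracle_scene()
        geom = scene.needle
        s1 = make_sphere_sq(8.0, (20.0, 10.0, 60.0), label="s1")
        s2 = make_sphere_sq(6.0, (-25.0, -15.0, 80.0), label="s2")
        gamma = 1.5
        bd = cfrw_for_needle(origin_target, geom, [s1, s2], [150.0],
                             gamma, 0.1, limits_full)

        def cone_feasible(direction, center, r):
            d = np.linalg.norm(center)
            cos_alpha = np.sqrt(1 - ((r + gamma) / d) ** 2)
            return direction @ (center / d) < cos_alpha

        rng = np.random.default_rng(4)
        mism = 0
        checked = 0
        for _ in range(400):
            theta = rng.uniform(0.02, 1.15)
            phi = rng.uniform(-np.pi, np.pi)
            traj = Trajectory.from_angles(origin_target, theta, phi,
                                          160.0 / np.cos(theta))
            want = (cone_feasible(traj.direction, s1.pose.translation, 8.0)
                    and cone_feasible(traj.direction, s2.pose.translation, 6.0))
            got = trajectory_in_cfrw(traj, bd)
            checked += 1
            if want != got:
                # tolerate disagreement only within the barrier-bias band
                d1 = planner.segment_surface_distance(
                    origin_target.compensated, traj.entry, s1)
                d2 = planner.segment_surface_distance(
                    origin_target.compensated, traj.entry, s2)
                assert min(abs(d1 - gamma), abs(d2 - gamma)) < 0.1
                mism += 1
        assert checked == 400
        assert mism <= 8

    def test_grid_seeding_finds_the_same_boundary(self, sphere_setup):
        """Interior-grid seeding with deduplication matches projection seeding."""
        scene, oracle = sphere_setup
        bd = cfrw_for_needle(scene.targets[0], scene.needle, scene.obstacles,
                             [150.0], 1.5, 0.1, scene.angle_limits,
                             seed_strategy="grid", grid_n=5, step=1.0)
        ls = bd.layers[0]
        assert len(ls.curves) == 1
        radius = np.linalg.norm(np.asarray(ls.curves[0]), axis=1).mean()
        assert radius == pytest.approx(oracle.circle_radius(150.0), abs=0.35)

    def test_fully_blocked_layer_flagged(self, origin_target, limits_full):
        """A huge obstacle right above the target blocks every trajectory."""
        scene, _ = make_sphere_oracle_scene()
        big = make_sphere_sq(60.0, (0.0, 0.0, 50.0), label="big")
        bd = cfrw_for_needle(origin_target, scene.needle, [big], [150.0],
                             1.5, 0.1, limits_full)
        assert bd.layers[0].fully_infeasible

    def test_membership_errors(self, sphere_setup):
        scene, _ = sphere_setup
        bd = CFRWBoundary(0, 1.5, 0.1, scene.targets[0], scene.angle_limits,
                          layers=[LayerCurveSet("o", 150.0, [])])
        flat = Trajectory(Target(np.array([0, 0, 50.0])),
                          np.array([100.0, 0.0, 50.0 + 1e-13]))
        with pytest.raises(ValueError):
            trajectory_in_cfrw(flat, bd)
        low = Trajectory(scene.targets[0], np.array([10.0, 0.0, 100.0]))
        with pytest.raises(ValueError, match="crosses none"):
            trajectory_in_cfrw(low, bd)
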