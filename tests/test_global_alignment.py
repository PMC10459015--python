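"""Pose-graph construction, error functions, and sparse LM fusion."""

import numpy as np
import pytest

from stemmap.evaluate import trajectory_rmse
from stemmap.geometry import rot2, wrap_angle
from stemmap.global_alignment import (
    GlobalState,
    GpsObservation,
    GraphError,
    LMConfig,
    OdometryEdge,
    UnresolvableOrientationError,
    anchor_gps,
    assemble_normal_equations,
    build_graph,
    default_gps_info,
    default_odometry_info,
    gps_error,
    gps_robust_weights,
    lm_optimize,
    odometry_error,
    recover_global,
    correspond_by_timestamp,
)
from stemmap.global_alignment import _objective
from stemmap.synthetic import (
    GpsNoiseSpec,
    WorldSpec,
    simulate_gps_track,
    simulate_world,
)

INFO3 = default_odometry_info()
INFO2 = default_gps_info()


def _se2_matrix(v):
    T = np.eye(3)
    T[:2, :2] = rot2(v[2])
    T[:2, 2] = v[:2]
    return T


def _random_graph(rng, n_poses=5, gps_at=(0, 2, 4)):
    edges = [
        OdometryEdge(i, rng.normal(0, 1.0, 3), INFO3) for i in range(n_poses - 1)
    ]
    poses = build_graph(edges) + rng.normal(0, 0.1, (n_poses, 3))
    gps = [GpsObservation(rng.normal(0, 3, 2), INFO2, i) for i in gps_at]
    return edges, poses, gps


class TestBuildGraph:
    def test_no_edges_single_zero_pose(self):
        assert np.array_equal(build_graph([]), np.zeros((1, 3)))

    def test_straight_line(self):
        edges = [OdometryEdge(i, [1, 0, 0], INFO3) for i in range(2)]
        assert np.allclose(build_graph(edges), [[0, 0, 0], [1, 0, 0], [2, 0, 0]])

    def test_quarter_turn_chain(self):
        edges = [
            OdometryEdge(0, [1, 0, np.pi / 2], INFO3),
            OdometryEdge(1, [1, 0, 0], INFO3),
        ]
        poses = build_graph(edges)
        assert np.allclose(poses[2], [1, 1, np.pi / 2])

    def test_nonconsecutive_edges_rejected(self):
        with pytest.raises(GraphError):
            build_graph([OdometryEdge(1, [1, 0, 0], INFO3)])


class TestAnchor:
    def test_single_fix_rejected(self):
        with pytest.raises(UnresolvableOrientationError):
            anchor_gps([GpsObservation([0, 0], INFO2, 0)])

    def test_translation_by_first_fix(self):
        gps = [
            GpsObservation([5, 5], INFO2, 0),
            GpsObservation([6, 7], INFO2, 1),
        ]
        anchored, g0 = anchor_gps(gps)
        assert np.allclose(g0, [5, 5])
        assert np.allclose(anchored[0].coord, [0, 0])
        assert np.allclose(anchored[1].coord, [1, 2])

    def test_anchor_then_recover_is_identity(self):
        gps = [
            GpsObservation([50, -20], INFO2, 0),
            GpsObservation([51, -18], INFO2, 1),
        ]
        anchored, g0 = anchor_gps(gps)
        poses = np.array([a.coord.tolist() + [0.0] for a in anchored])
        state = GlobalState(phi=0.0, poses=poses, anchor=g0)
        recovered = recover_global(state)
        assert np.allclose(recovered[:, :2], [[50, -20], [51, -18]])


class TestErrorFunctions:
    def test_zero_on_composed_chain(self, rng):
        edges = [OdometryEdge(i, rng.normal(0, 1, 3), INFO3) for i in range(3)]
        poses = build_graph(edges)
        for e in edges:
            r = odometry_error(poses[e.i], poses[e.i + 1], e.motion)
            assert np.allclose(r, 0, atol=1e-12)

    def test_unit_translation_error(self):
        r = odometry_error([0, 0, 0], [1, 0, 0], [0, 0, 0])
        assert np.allclose(r, [1, 0, 0])

    def test_matches_transform_product_oracle(self, rng):
        for _ in range(10):
            vi, vj = rng.normal(0, 2, 3), rng.normal(0, 2, 3)
            motion = rng.normal(0, 1, 3)
            M = (
                np.linalg.inv(_se2_matrix(motion))
                @ np.linalg.inv(_se2_matrix(vi))
                @ _se2_matrix(vj)
            )
            r = odometry_error(vi, vj, motion)
            assert np.allclose(r[:2], M[:2, 2], atol=1e-12)
            ang = np.arctan2(M[1, 0], M[0, 0])
            assert np.isclose(wrap_angle(r[2] - ang), 0, atol=1e-12)

    def test_gps_error_zero_cases(self):
        assert np.allclose(gps_error([1, 2, 0.3], 0.0, [1, 2]), 0)
        assert np.allclose(gps_error([1, 0, 0], np.pi / 2, [0, 1]), 0, atol=1e-12)

    def test_gps_error_matches_rotation_oracle(self, rng):
        for _ in range(10):
            v = rng.normal(0, 5, 3)
            phi = rng.uniform(-np.pi, np.pi)
            g = rng.normal(0, 5, 2)
            assert np.allclose(gps_error(v, phi, g), rot2(phi) @ v[:2] - g)


class TestNormalEquations:
    def test_gradient_vanishes_at_zero_error(self, rng):
        edges = [OdometryEdge(i, rng.normal(0, 1, 3), INFO3) for i in range(4)]
        poses = build_graph(edges)
        gps = [GpsObservation(poses[i, :2], INFO2, i) for i in (0, 2, 4)]
        state = GlobalState(phi=0.0, poses=poses, anchor=np.zeros(2))
        H, b = assemble_normal_equations(state, edges, gps)
        assert np.allclose(b, 0, atol=1e-10)

    def test_blocks_match_finite_differences(self, rng):
        """H and b agree with numerical derivatives of the objective."""
        edges, poses, gps = _random_graph(rng)
        state = GlobalState(phi=0.4, poses=poses, anchor=np.zeros(2))
        H, b = assemble_normal_equations(state, edges, gps)
        x0 = state.as_vector()
        eps = 1e-6
        for k in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += eps
            xm[k] -= eps
            up = _objective(GlobalState.from_vector(xp, state.anchor), edges, gps, None)
            dn = _objective(GlobalState.from_vector(xm, state.anchor), edges, gps, None)
            grad_fd = (up - dn) / (2 * eps)
            assert np.isclose(2 * b[k], grad_fd, rtol=1e-5, atol=1e-5)

    def test_sparse_equals_dense_stacked_jacobian_oracle(self, rng):
        """Tiny graph: H equals J^T Q J built by numerically stacking all
        residual Jacobians densely."""
        edges, poses, gps = _random_graph(rng, n_poses=3, gps_at=(0, 2))
        state = GlobalState(phi=-0.2, poses=poses, anchor=np.zeros(2))
        H, b = assemble_normal_equations(state, edges, gps)

        def residuals(x):
            st = GlobalState.from_vector(x, state.anchor)
            parts = []
            for e in edges:
                L = np.linalg.cholesky(e.info)
                parts.append(
                    L.T @ odometry_error(st.poses[e.i], st.poses[e.i + 1], e.motion)
                )
            for g in gps:
                L = np.linalg.cholesky(g.info)
                parts.append(L.T @ gps_error(st.poses[g.pose_index], st.phi, g.coord))
            return np.concatenate(parts)

        x0 = state.as_vector()
        r0 = residuals(x0)
        J = np.zeros((len(r0), len(x0)))
        eps = 1e-7
        for k in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += eps
            xm[k] -= eps
            J[:, k] = (residuals(xp) - residuals(xm)) / (2 * eps)
        assert np.allclose(H.toarray(), J.T @ J, atol=1e-5)
        assert np.allclose(b, J.T @ r0, atol=1e-6)


class TestLMOptimize:
    def test_zero_noise_terminates_at_start(self, rng):
        edges = [OdometryEdge(i, rng.normal(0, 1, 3), INFO3) for i in range(5)]
        poses = build_graph(edges)
        gps = [GpsObservation(poses[i, :2], INFO2, i) for i in range(6)]
        state0 = GlobalState(phi=0.0, poses=poses, anchor=np.zeros(2))
        cfg = LMConfig(phi_grid_init=False)
        state, hist = lm_optimize(state0, edges, gps, cfg)
        assert np.allclose(state.poses, poses, atol=1e-9)
        assert _objective(state, edges, gps, None) < 1e-16

    def test_recovers_rigid_rotation(self, rng):
        """Perfect odometry; GPS is the track rotated by phi0 = 0.3 rad."""
        spec = WorldSpec(seed=5, path_length_m=60, stem_count=0, initial_heading=0.4)
        world = simulate_world(spec, default_odometry_info(0.002, 1e-4))
        chain = build_graph(world.edges)
        phi0 = 0.3
        coords = chain[:, :2] @ rot2(phi0).T
        gps = [
            GpsObservation(coords[i], default_gps_info(1.0), i)
            for i in range(len(chain))
        ]
        anchored, g0 = anchor_gps(gps)
        state, _ = lm_optimize(
            GlobalState(0.0, chain, g0),
            world.edges,
            anchored,
            LMConfig(step_tol=1e-9),
        )
        aligned = recover_global(state)
        truth = np.column_stack([coords, wrap_angle(chain[:, 2] + phi0)])
        assert trajectory_rmse(aligned, truth) < 1e-6

    def test_objective_nonincreasing_over_accepted_steps(self, rng):
        spec = WorldSpec(seed=8, path_length_m=80, stem_count=0)
        world = simulate_world(spec, default_odometry_info(0.01, 1e-3))
        gps, _ = simulate_gps_track(world.trajectory, GpsNoiseSpec(sigma_m=5, seed=2))
        anchored, g0 = anchor_gps(gps)
        _, hist = lm_optimize(
            GlobalState(0.0, build_graph(world.edges), g0), world.edges, anchored
        )
        obj = hist["objective"]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(obj, obj[1:]))

    def test_gauge_property_constant_gps_shift(self, rng):
        """Adding a constant to all GPS coordinates shifts the recovered
        track by the same constant."""
        spec = WorldSpec(seed=11, path_length_m=60, stem_count=0)
        world = simulate_world(spec, default_odometry_info(0.002, 1e-4))
        gps, _ = simulate_gps_track(world.trajectory, GpsNoiseSpec(sigma_m=2, seed=3))
        shift = np.array([137.0, -42.0])
        shifted = [
            GpsObservation(g.coord + shift, g.info, g.pose_index) for g in gps
        ]
        outs = []
        for obs_list in (gps, shifted):
            anchored, g0 = anchor_gps(obs_list)
            st, _ = lm_optimize(
                GlobalState(0.0, build_graph(world.edges), g0),
                world.edges,
                anchored,
                LMConfig(step_tol=1e-8),
            )
            outs.append(recover_global(st))
        assert np.allclose(outs[1][:, :2] - outs[0][:, :2], shift, atol=1e-6)

    def test_sparse_path_equals_dense_on_small_graph(self, rng):
        edges, poses, gps = _random_graph(rng, n_poses=8, gps_at=(0, 3, 7))
        state0 = GlobalState(0.0, poses, np.zeros(2))
        outs = []
        for threshold in (0, 10_000):  # force sparse, then dense
            cfg = LMConfig(dense_threshold=threshold, phi_grid_init=False)
            st, _ = lm_optimize(state0, edges, gps, cfg)
            outs.append(st.as_vector())
        assert np.allclose(outs[0], outs[1], atol=1e-8)

    def test_robust_weights_suppress_outliers(self, rng):
        spec = WorldSpec(seed=21, path_length_m=150, stem_count=0)
        world = simulate_world(spec, default_odometry_info(5e-4, 2e-6))
        tracks = []
        for frac in (0.0, 0.05):
            gps, _ = simulate_gps_track(
                world.trajectory,
                GpsNoiseSpec(sigma_m=5, outlier_fraction=frac, seed=77),
            )
            anchored, g0 = anchor_gps(gps)
            st, _ = lm_optimize(
                GlobalState(0.0, build_graph(world.edges), g0),
                world.edges,
                anchored,
                LMConfig(robust_gps=True),
            )
            tracks.append(recover_global(st))
        diff = trajectory_rmse(tracks[0], tracks[1])
        assert diff < 0.05

    def test_fewer_than_two_fixes_rejected(self, rng):
        edges = [OdometryEdge(0, [1, 0, 0], INFO3)]
        state = GlobalState(0.0, build_graph(edges), np.zeros(2))
        with pytest.raises(UnresolvableOrientationError):
            lm_optimize(state, edges, [GpsObservation([0, 0], INFO2, 0)], LMConfig())


class TestRecoverAndWeights:
    def test_recover_identity(self):
        st = GlobalState(0.0, np.array([[1.0, 2.0, 0.5]]), np.zeros(2))
        assert np.allclose(recover_global(st), [[1, 2, 0.5]])

    def test_recover_half_turn_with_anchor(self):
        st = GlobalState(np.pi, np.array([[1.0, 0.0, 0.0]]), np.array([10.0, 10.0]))
        out = recover_global(st)
        assert np.allclose(out[0], [9, 10, np.pi])

    def test_robust_weights_unit_when_consistent(self):
        poses = np.array([[0.0, 0, 0], [1, 0, 0]])
        gps = [GpsObservation(poses[i, :2], INFO2, i) for i in range(2)]
        st = GlobalState(0.0, poses, np.zeros(2))
        assert np.allclose(gps_robust_weights(st, gps), 1.0)

    def test_timestamp_correspondence(self):
        frames = np.arange(5) / 10.0
        gps_times = np.array([0.01, 0.21, 5.0])
        pairs = correspond_by_timestamp(frames, gps_times)
        assert pairs == [(0, 0), (2, 1)]
        same = correspond_by_timestamp(frames, frames)
        assert same == [(i, i) for i in range(5)]
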