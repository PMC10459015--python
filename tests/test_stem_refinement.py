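"""Stem association, cluster initialization, and joint refinement."""

import numpy as np
import pytest

from stemmap.evaluate import evaluate_stem_map, trajectory_rmse
from stemmap.geometry import rot2
from stemmap.global_alignment import (
    GlobalState,
    GpsObservation,
    LMConfig,
    OdometryEdge,
    anchor_gps,
    build_graph,
    default_gps_info,
    default_odometry_info,
    lm_optimize,
    recover_global,
)
from stemmap.stem_refinement import (
    AugmentedState,
    ClusterAssignment,
    EmptyMapError,
    StemObservation,
    assemble_refinement_system,
    cluster_centers,
    dbscan_cluster,
    observations_to_world,
    refine_map,
    stem_error,
)
from stemmap.stem_refinement import _refinement_objective, _stem_terms
from stemmap.synthetic import (
    GpsNoiseSpec,
    WorldSpec,
    simulate_gps_track,
    simulate_stem_observations,
    simulate_world,
)


def _obs(i, fwd, lat, q=0, info=None):
    return StemObservation(i, q, np.array([fwd, lat], float),
                           np.eye(2) if info is None else info)


def brute_force_dbscan(points, radius, min_pts):
    """Reference density clustering: region queries + BFS expansion."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    neighbors = [np.nonzero(d[i] <= radius)[0] for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.zeros(n, dtype=int)
    visited = np.zeros(n, dtype=bool)
    current = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        current += 1
        stack = [i]
        visited[i] = True
        labels[i] = current
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if labels[k] == 0:
                    labels[k] = current
                if core[k] and not visited[k]:
                    visited[k] = True
                    stack.append(k)
    return labels


class TestObservationTransform:
    def test_identity_pose(self):
        w = observations_to_world([_obs(0, 1, 2)], np.array([[0.0, 0, 0]]))
        assert np.allclose(w, [[1, 2]])

    def test_quarter_turn_pose(self):
        w = observations_to_world([_obs(0, 1, 0)], np.array([[10.0, 0, np.pi / 2]]))
        assert np.allclose(w, [[10, 1]], atol=1e-12)

    def test_matches_rotation_matrix_oracle(self, rng):
        poses = rng.normal(0, 5, (4, 3))
        obs = [_obs(i, abs(rng.normal(3, 1)), rng.normal(0, 2)) for i in range(4)]
        w = observations_to_world(obs, poses)
        for k, o in enumerate(obs):
            p = poses[o.pose_index]
            assert np.allclose(w[k], rot2(p[2]) @ o.offset + p[:2])

    def test_inverse_of_stem_error(self, rng):
        pose = rng.normal(0, 3, 3)
        o = _obs(0, 2.5, -0.7)
        world = observations_to_world([o], pose[None, :])[0]
        assert np.allclose(stem_error(pose, world, o), 0, atol=1e-12)

    def test_forward_component_must_be_positive(self):
        with pytest.raises(ValueError):
            _obs(0, -1.0, 0.0)


class TestClustering:
    def test_two_separated_groups(self, rng):
        a = rng.normal(0, 0.05, (20, 2))
        b = rng.normal(0, 0.05, (20, 2)) + [10, 0]
        assignment = dbscan_cluster(np.vstack([a, b]), radius=1.0, min_pts=10)
        assert assignment.n_clusters == 2
        assert np.all(assignment.labels > 0)
        assert len(set(assignment.labels[:20])) == 1
        assert len(set(assignment.labels[20:])) == 1

    def test_isolated_points_are_outliers(self, rng):
        pts = np.arange(10).reshape(5, 2) * 50.0
        assignment = dbscan_cluster(pts, radius=1.0, min_pts=10)
        assert np.all(assignment.labels == 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        centers = rng.uniform(0, 30, (6, 2))
        pts = np.vstack(
            [c + rng.normal(0, 0.2, (rng.integers(3, 20), 2)) for c in centers]
            + [rng.uniform(0, 30, (10, 2))]
        )
        ours = dbscan_cluster(pts, radius=0.8, min_pts=5).labels
        ref = brute_force_dbscan(pts, 0.8, 5)
        # identical partitions up to label permutation
        assert np.array_equal(ours == 0, ref == 0)
        mapping = {}
        for o, r in zip(ours, ref):
            if o == 0:
                continue
            assert mapping.setdefault(o, r) == r
        assert len(set(mapping.values())) == len(mapping)

    def test_cluster_sizes_respect_min_pts(self, rng):
        pts = rng.uniform(0, 20, (200, 2))
        assignment = dbscan_cluster(pts, radius=1.0, min_pts=10)
        for lab in assignment.label_set:
            assert np.sum(assignment.labels == lab) >= 10

    def test_rigid_invariance(self, rng):
        pts = rng.uniform(0, 20, (150, 2))
        base = dbscan_cluster(pts, radius=1.0, min_pts=5).labels
        moved = pts @ rot2(0.77).T + [100, -50]
        assert np.array_equal(base, dbscan_cluster(moved, 1.0, 5).labels)


class TestClusterCenters:
    def test_simple_mean(self):
        pts = np.array([[0.0, 0], [2, 0]])
        sm = cluster_centers(pts, ClusterAssignment(labels=np.array([1, 1])))
        assert np.allclose(sm.centers, [[1, 0]])
        assert sm.counts[0] == 2

    def test_outliers_excluded(self):
        pts = np.array([[0.0, 0], [2, 0], [100, 100]])
        sm = cluster_centers(pts, ClusterAssignment(labels=np.array([1, 1, 0])))
        assert np.allclose(sm.centers, [[1, 0]])

    def test_means_match_loop_oracle(self, rng):
        pts = rng.normal(0, 5, (40, 2))
        labels = rng.integers(0, 4, 40)
        if not np.any(labels > 0):
            labels[0] = 1
        sm = cluster_centers(pts, ClusterAssignment(labels=labels))
        for k, lab in enumerate(sorted(set(labels) - {0})):
            assert np.allclose(sm.centers[k], pts[labels == lab].mean(axis=0))

    def test_empty_map_signaled(self):
        with pytest.raises(EmptyMapError):
            cluster_centers(np.zeros((3, 2)), ClusterAssignment(labels=np.zeros(3, int)))


class TestRefinementSystem:
    def test_stem_error_at_identity_pose(self):
        r = stem_error([0, 0, 0], [3.0, 1.0], _obs(0, 2.0, 0.5))
        assert np.allclose(r, [1.0, 0.5])

    def test_blocks_match_finite_differences(self, rng):
        pose = rng.normal(0, 2, 3)
        center = rng.normal(0, 2, 2)
        o = _obs(0, 2.0, 0.5)
        aug = AugmentedState(poses=pose[None, :], centers=center[None, :])
        r, E, F, Q, _, _ = _stem_terms(aug, [o], ClusterAssignment(np.array([1])))
        eps = 1e-7
        for k in range(3):
            pp, pm = pose.copy(), pose.copy()
            pp[k] += eps
            pm[k] -= eps
            fd = (stem_error(pp, center, o) - stem_error(pm, center, o)) / (2 * eps)
            assert np.allclose(E[0][:, k], fd, rtol=1e-6, atol=1e-6)
        for k in range(2):
            cp, cm = center.copy(), center.copy()
            cp[k] += eps
            cm[k] -= eps
            fd = (stem_error(pose, cp, o) - stem_error(pose, cm, o)) / (2 * eps)
            assert np.allclose(F[0][:, k], fd, rtol=1e-6, atol=1e-6)

    def test_gradient_vanishes_at_zero_residual(self, rng):
        edges = [OdometryEdge(i, rng.normal(0, 1, 3), default_odometry_info()) for i in range(3)]
        poses = build_graph(edges)
        gps = [GpsObservation(poses[i, :2], default_gps_info(), i) for i in (0, 3)]
        obs = [_obs(i, 2.0, 0.3) for i in range(4)]
        world = observations_to_world(obs, poses)
        # one cluster per observation position collapsed to the exact stems
        aug = AugmentedState(poses=poses, centers=world[:1])
        assignment = ClusterAssignment(labels=np.array([1, 0, 0, 0]))
        aug.centers = world[:1]
        H, b = assemble_refinement_system(aug, edges, gps, obs, assignment)
        assert np.allclose(b, 0, atol=1e-10)

    def test_sparse_equals_dense_stacked_oracle(self, rng):
        """Tiny instance: sparse system equals numerically stacked J^T Q J."""
        edges = [OdometryEdge(i, rng.normal(0, 1, 3), default_odometry_info()) for i in range(2)]
        poses = build_graph(edges) + rng.normal(0, 0.05, (3, 3))
        gps = [GpsObservation(rng.normal(0, 1, 2), default_gps_info(), i) for i in (0, 2)]
        obs = [_obs(i % 3, 2.0 + 0.2 * i, rng.normal(0, 0.5), q=i) for i in range(6)]
        labels = np.array([1, 2, 1, 2, 1, 2])
        assignment = ClusterAssignment(labels=labels)
        centers = rng.normal(0, 2, (2, 2))
        aug = AugmentedState(poses=poses, centers=centers)
        H, b = assemble_refinement_system(aug, edges, gps, obs, assignment)

        def residuals(x):
            st = AugmentedState.from_vector(x, 3)
            parts = []
            from stemmap.global_alignment import odometry_error

            for e in edges:
                L = np.linalg.cholesky(e.info)
                parts.append(L.T @ odometry_error(st.poses[e.i], st.poses[e.i + 1], e.motion))
            for g in gps:
                L = np.linalg.cholesky(g.info)
                parts.append(L.T @ (st.poses[g.pose_index, :2] - g.coord))
            for o, lab in zip(obs, labels):
                L = np.linalg.cholesky(o.info)
                parts.append(L.T @ stem_error(st.poses[o.pose_index], st.centers[lab - 1], o))
            return np.concatenate(parts)

        x0 = aug.as_vector()
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


class TestRefineMap:
    def _noiseless_setup(self, seed=9, path=200.0):
        spec = WorldSpec(seed=seed, path_length_m=path, speed_mps=1.0)
        world = simulate_world(spec, default_odometry_info(5e-4, 2e-6))
        gps, _ = simulate_gps_track(world.trajectory, GpsNoiseSpec(sigma_m=0.0, seed=1))
        obs = simulate_stem_observations(world.trajectory, world.stems, spec, noise_scale=0.0)
        anchored, g0 = anchor_gps(gps)
        st, _ = lm_optimize(
            GlobalState(0.0, build_graph(world.edges), g0),
            world.edges,
            anchored,
            LMConfig(step_tol=1e-9),
        )
        return world, gps, obs, recover_global(st)

    def test_noiseless_world_is_fixed_point(self):
        world, gps, obs, aligned = self._noiseless_setup()
        result = refine_map(aligned, world.edges, gps, obs, cfg=LMConfig(step_tol=1e-9))
        assert trajectory_rmse(result.poses, world.trajectory) < 1e-6
        ev = evaluate_stem_map(result.stem_map.centers, world.stems)
        assert ev.rmse < 1e-6
        assert ev.false_positives == 0

    def test_objective_nonincreasing(self):
        spec = WorldSpec(seed=13, path_length_m=150, speed_mps=1.0)
        world = simulate_world(spec, default_odometry_info(0.01, 1e-3))
        gps, _ = simulate_gps_track(world.trajectory, GpsNoiseSpec(sigma_m=5, seed=4))
        obs = simulate_stem_observations(world.trajectory, world.stems, spec)
        anchored, g0 = anchor_gps(gps)
        st, _ = lm_optimize(
            GlobalState(0.0, build_graph(world.edges), g0), world.edges, anchored
        )
        result = refine_map(recover_global(st), world.edges, gps, obs)
        objs = result.history["objective"]
        assert len(objs) >= 1
        assert all(b <= a * (1 + 1e-12) for a, b in zip(objs, objs[1:]))
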