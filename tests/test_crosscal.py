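import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from moiretrack.crosscal import (PhantomSpec, PointCorrespondences,
                                 preprocess_camera_points, preprocessing_transform,
                                 repeatability, solve_rigid_transform, apply_transform)
from moiretrack.geometry import Pose6DOF, RigidTransform


def _random_transform(rng, angle_scale=30.0, trans_scale=50.0):
    R = Rotation.from_rotvec(rng.normal(0, np.radians(angle_scale), 3)).as_matrix()
    return RigidTransform(rotation=R, translation=rng.normal(0, trans_scale, 3))


class TestRigidSolve:
    def test_identity_when_target_equals_source(self):
        pts = PhantomSpec().aruco_positions()
        T, fre = solve_rigid_transform(PointCorrespondences(pts, pts))
        assert np.allclose(T.matrix(), np.eye(4), atol=1e-12)
        assert fre == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_random_transform(self):
        rng = np.random.default_rng(0)
        src = PhantomSpec().aruco_positions()
        for _ in range(5):
            T_true = _random_transform(rng)
            dst = T_true.apply(src)
            T, fre = solve_rigid_transform(PointCorrespondences(src, dst))
            assert np.abs(T.matrix() - T_true.matrix()).max() < 1e-9
            assert fre < 1e-9

    def test_never_returns_reflection(self):
        # a near-planar set plus large noise tempts the SVD into det = -1
        rng = np.random.default_rng(1)
        src = PhantomSpec().well_positions()
        for _ in range(20):
            dst = _random_transform(rng).apply(src) + rng.normal(0, 20.0, src.shape)
            T, _ = solve_rigid_transform(PointCorrespondences(src, dst))
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(2)
        src = PhantomSpec().aruco_positions()
        T_true = _random_transform(rng)
        dst = T_true.apply(src) + rng.normal(0, 0.3, src.shape)
        T, _ = solve_rigid_transform(PointCorrespondences(src, dst))
        R_ref, _ = Rotation.align_vectors(dst - dst.mean(axis=0),
                                          src - src.mean(axis=0))
        assert np.abs(T.rotation - R_ref.as_matrix()).max() < 1e-8

    def test_three_point_case_matches_brute_force(self):
        # independent oracle: direct minimisation of the pair-distance SSE
        from scipy.optimize import minimize

        rng = np.random.default_rng(3)
        src = np.array([[0.0, 0, 0], [30, 0, 0], [0, 25, 0]])
        T_true = _random_transform(rng, 10, 10)
        dst = T_true.apply(src) + rng.normal(0, 0.2, src.shape)
        T, fre = solve_rigid_transform(PointCorrespondences(src, dst))

        def cost(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            return np.sum((src @ R.T + p[3:] - dst) ** 2)

        res = minimize(cost, np.zeros(6), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert cost(np.concatenate([Rotation.from_matrix(T.rotation).as_rotvec(),
                                    T.translation])) <= res.fun + 1e-9
        assert fre > 0

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            PointCorrespondences(src, src)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        spec = PhantomSpec()
        src = spec.aruco_positions()
        dst = _random_transform(rng).apply(src) + rng.normal(0, 0.3, src.shape)
        corr = PointCorrespondences(src, dst, labels=list(range(15)))
        T1, _ = solve_rigid_transform(corr)
        perm = rng.permutation(15)
        corr2 = PointCorrespondences(src[perm], dst[perm], labels=list(perm))
        T2, _ = solve_rigid_transform(corr2)
        assert np.abs(T1.matrix() - T2.matrix()).max() < 1e-12

    def test_dropping_redundant_points_noiseless(self):
        # losing up to 12 of the 15 pairs leaves the noiseless solution unchanged
        rng = np.random.default_rng(5)
        src = PhantomSpec().aruco_positions()
        T_true = _random_transform(rng)
        dst = T_true.apply(src)
        full, _ = solve_rigid_transform(PointCorrespondences(src, dst))
        idx = [0, 4, 12]  # non-collinear 3-subset
        sub, _ = solve_rigid_transform(PointCorrespondences(src[idx], dst[idx]))
        assert np.abs(full.matrix() - sub.matrix()).max() < 1e-9

    def test_fre_decreases_with_more_points(self):
        # expectation over repeats: FRE (residual RMS) grows with N, but the
        # transform parameter error shrinks from 3 -> 15 points
        rng = np.random.default_rng(6)
        src15 = PhantomSpec().aruco_positions()
        errs = {3: [], 15: []}
        for _ in range(40):
            T_true = _random_transform(rng, 5, 5)
            for n in (3, 15):
                idx = [0, 4, 12] if n == 3 else list(range(15))
                dst = T_true.apply(src15[idx]) + rng.normal(0, 0.3, (n, 3))
                T, _ = solve_rigid_transform(PointCorrespondences(src15[idx], dst))
                errs[n].append(np.linalg.norm(T.translation - T_true.translation))
        assert np.mean(errs[15]) < np.mean(errs[3])


class TestPreprocessing:
    def test_offset_step_alone(self):
        out = preprocess_camera_points(np.zeros((1, 3)), mirror_fold=False,
                                       frame_convention=False, z_offset=True)
        assert np.allclose(out, [[0, 0, -3000]])

    def test_full_chain_inverse_round_trip(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 100, (15, 3))
        T = preprocessing_transform()
        assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-9)

    def test_each_step_toggleable(self):
        T_all = preprocessing_transform()
        T_no_mirror = preprocessing_transform(mirror_fold=False)
        assert not np.allclose(T_all.matrix(), T_no_mirror.matrix())
        assert np.allclose(
            preprocessing_transform(False, False, False).matrix(), np.eye(4))

    def test_preprocessing_leaves_small_residual_for_nominal_geometry(self):
        # camera points generated with the nominal mirror/frame/offset chain
        # plus a small physical misalignment: after preprocessing the residual
        # transform is small (|rot| < 10 deg, |trans| < 100 mm)
        rng = np.random.default_rng(8)
        spec = PhantomSpec()
        mri_pts = spec.well_positions()
        residual_true = RigidTransform.from_euler(-5.0, 0.2, 4.6,
                                                  translation=(-6.3, -18.6, -67.5))
        T_pre = preprocessing_transform()
        cam_pts = T_pre.inverse().apply(residual_true.inverse().apply(mri_pts))
        corrected = preprocess_camera_points(cam_pts)
        T, fre = solve_rigid_transform(PointCorrespondences(corrected, mri_pts))
        pose = T.to_pose()
        assert np.all(np.abs([pose.pitch, pose.yaw, pose.roll]) < 10.0)
        assert np.all(np.abs([pose.tx, pose.ty, pose.tz]) < 100.0)
        assert fre < 1e-9


class TestApplyTransform:
    def test_identity_and_inverse_round_trip(self):
        rng = np.random.default_rng(9)
        T = _random_transform(rng)
        pts = rng.normal(0, 10, (6, 3))
        assert np.allclose(apply_transform(RigidTransform.identity(), pts), pts)
        assert np.allclose(apply_transform(T.inverse(), apply_transform(T, pts)),
                           pts, atol=1e-10)

    def test_composition_matches_matrix_oracle(self):
        rng = np.random.default_rng(10)
        A, B = _random_transform(rng), _random_transform(rng)
        pts = rng.normal(0, 10, (4, 3))
        via_compose = apply_transform(apply_transform(A, B), pts)
        h = np.column_stack([pts, np.ones(4)])
        via_matrix = (h @ (A.matrix() @ B.matrix()).T)[:, :3]
        assert np.allclose(via_compose, via_matrix, atol=1e-9)

    def test_pose_argument(self):
        T = RigidTransform(translation=[1.0, 2.0, 3.0])
        out = apply_transform(T, Pose6DOF())
        assert (out.tx, out.ty, out.tz) == (1.0, 2.0, 3.0)


class TestRepeatability:
    def test_identical_trials_are_all_zero(self):
        T = RigidTransform.from_euler(1, 2, 3, translation=(4, 5, 6))
        table = repeatability([T, T, T])
        assert np.allclose(table["max_deviation"], 0.0, atol=1e-12)
        assert np.allclose(table["sd"], 0.0, atol=1e-12)

    def test_one_mm_z_difference(self):
        T1 = RigidTransform()
        T2 = RigidTransform(translation=[0, 0, 1.0])
        table = repeatability([T1, T2])
        assert table.loc["z_mm", "max_deviation"] == pytest.approx(0.5)
        assert np.allclose(table.drop("z_mm")["max_deviation"], 0.0, atol=1e-12)

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            repeatability([RigidTransform()])

    def test_five_noisy_trials_stay_under_thresholds(self):
        # five simulated cross-calibrations with 0.3 mm point noise: every
        # per-DOF max deviation under 1 mm / 1 deg
        rng = np.random.default_rng(11)
        spec = PhantomSpec()
        mri_pts = spec.well_positions()
        residual = RigidTransform.from_euler(-5.2, 0.2, 4.6,
                                             translation=(-6.3, -18.6, -67.5))
        trials = []
        for _ in range(5):
            placement = _random_transform(rng, 3.0, 15.0)  # phantom repositioning
            cam = preprocessing_transform().inverse().apply(
                residual.inverse().apply(placement.apply(mri_pts)))
            cam = cam + rng.normal(0, 0.3, cam.shape)
            mri = placement.apply(mri_pts) + rng.normal(0, 0.3, mri_pts.shape)
            T, _ = solve_rigid_transform(
                PointCorrespondences(preprocess_camera_points(cam), mri))
            trials.append(T)
        table = repeatability(trials)
        assert np.all(table.loc[["x_mm", "y_mm", "z_mm"], "max_deviation"] < 1.0)
        assert np.all(table.loc[["pitch_deg", "yaw_deg", "roll_deg"],
                                "max_deviation"] < 1.0)
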