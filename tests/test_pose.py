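import numpy as np
import pytest

from moiretrack import Pose6DOF
from moiretrack.geometry import RigidTransform
from moiretrack.pose import (CameraIntrinsics, PoseTrace, StereoRig, fuse_pose,
                             lowpass_trace, solve_inplane_pnp, solve_planar_pnp,
                             track_sequence, triangulate_points)
from moiretrack.scene import (RenderOptions, external_camera, external_stereo,
                              render_marker_view)

from conftest import pose_offset


@pytest.fixture(scope="module")
def stereo():
    return external_stereo()


def _project_corners(spec, cam, pose):
    obj3 = np.column_stack([spec.checkerboard_inner_corners(),
                            np.zeros(35)])
    world = pose.to_transform().apply(obj3)
    return cam.intrinsics.project(cam.world_to_cam.apply(world))


class TestCameraModel:
    def test_distortion_round_trip(self):
        intr = CameraIntrinsics(fx=1000, fy=1000, cx=360, cy=240,
                                distortion=[-0.2, 0.05, 1e-3, -5e-4, 0.0])
        pts = np.random.default_rng(0).uniform(-0.2, 0.2, (50, 2))
        cam = np.column_stack([pts * 500, np.full(50, 500.0)])
        px = intr.project(cam)
        back = intr.undistort_points(px)
        assert np.allclose(back, pts, atol=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CameraIntrinsics(fx=-1, fy=1, cx=0, cy=0)
        with pytest.raises(ValueError):
            CameraIntrinsics(fx=10, fy=10, cx=5000, cy=240)


class TestPlanarPnP:
    def test_exact_recovery_from_noiseless_corners(self, spec, camera):
        pose = Pose6DOF(tx=0.3, ty=-0.4, roll=1.2)
        px = _project_corners(spec, camera, pose)
        res = solve_inplane_pnp(px, camera.intrinsics, spec)
        world = (camera.world_to_cam.inverse() @ res.transform).to_pose()
        assert world.tx == pytest.approx(0.3, abs=1e-4)
        assert world.ty == pytest.approx(-0.4, abs=1e-4)
        assert world.roll == pytest.approx(1.2, abs=1e-4)
        assert res.reprojection_rms < 1e-6
        assert res.reliable == ("tx", "ty", "roll")

    def test_x_and_roll_increments_under_corner_noise(self, spec, camera):
        # Table-1-style benchtop increments: 0.1 mm X and 0.5 deg roll with
        # 0.5 px corner noise
        rng = np.random.default_rng(2)
        cw = camera.world_to_cam.inverse()

        def measured(pose):
            px = _project_corners(spec, camera, pose) + rng.normal(0, 0.5, (35, 2))
            return (cw @ solve_inplane_pnp(px, camera.intrinsics, spec).transform).to_pose()

        base = Pose6DOF(tx=0.1, ty=-0.2, roll=0.3)
        dx = [measured(pose_offset(base, tx=0.1)).tx - measured(base).tx
              for _ in range(30)]
        dr = [measured(pose_offset(base, roll=0.5)).roll - measured(base).roll
              for _ in range(30)]
        assert np.mean(dx) == pytest.approx(0.1, abs=0.02)
        assert np.mean(dr) == pytest.approx(0.5, abs=0.15)

    def test_through_plane_instability_pattern(self, spec, camera):
        # monocular planar PnP at a ~1.5 degree FOV: pitch/yaw scatter is
        # orders of magnitude above the in-plane scatter
        rng = np.random.default_rng(3)
        base = Pose6DOF(tx=0.1, ty=-0.2, roll=0.3)
        poses = []
        for _ in range(40):
            px = _project_corners(spec, camera, base) + rng.normal(0, 0.5, (35, 2))
            poses.append(solve_inplane_pnp(px, camera.intrinsics, spec).pose)
        pitch_sd = np.std([p.pitch for p in poses])
        tx_sd = np.std([p.tx for p in poses])
        assert pitch_sd > 0.05
        assert tx_sd < 0.01

    def test_too_few_correspondences_rejected(self, spec, camera):
        with pytest.raises(ValueError):
            solve_planar_pnp(np.zeros((4, 2)), np.zeros((4, 2)), camera.intrinsics)


class TestTriangulation:
    def test_exact_inverse_of_projection(self, spec, stereo):
        rig, camL, camR = stereo
        rng = np.random.default_rng(1)
        pts = rng.uniform(-25, 25, (20, 3)) * [1, 1, 0.2]
        pl = camL.intrinsics.project(camL.world_to_cam.apply(pts))
        pr = camR.intrinsics.project(camR.world_to_cam.apply(pts))
        rec = triangulate_points(pl, pr, rig)
        truth = camL.world_to_cam.apply(pts)
        assert np.abs(rec - truth).max() < 1e-6

    def test_matches_ray_intersection_oracle(self, stereo):
        # independent oracle: least-squares intersection of the two viewing rays
        rig, camL, camR = stereo
        pts = np.array([[3.0, -4.0, 1.0], [-10.0, 5.0, -2.0]])
        pl = camL.intrinsics.project(camL.world_to_cam.apply(pts))
        pr = camR.intrinsics.project(camR.world_to_cam.apply(pts))
        rec = triangulate_points(pl, pr, rig)
        for k in range(len(pts)):
            oracle = _ray_intersection(camL, camR, pl[k], pr[k])
            assert np.allclose(rec[k], camL.world_to_cam.apply(oracle), atol=1e-6)

    def test_mismatched_counts_rejected(self, stereo):
        rig = stereo[0]
        with pytest.raises(ValueError):
            triangulate_points(np.zeros((3, 2)), np.zeros((2, 2)), rig)

    def test_parallel_rays_rejected(self):
        intr = CameraIntrinsics(fx=1000, fy=1000, cx=360, cy=240)
        rig = StereoRig(left=intr, right=intr,
                        extrinsic=RigidTransform(translation=[1e-3, 0, 0]))
        with pytest.raises(ValueError):
            triangulate_points([[360, 240]], [[360, 240]], rig)


def _ray_intersection(camL, camR, pxl, pxr):
    """Brute-force least-squares intersection of two pixel rays (world frame)."""
    out = []
    A, b = [], []
    for cam, px in ((camL, pxl), (camR, pxr)):
        c = cam.center
        xn = cam.intrinsics.undistort_points(px)[0]
        d = cam.world_to_cam.rotation.T @ np.array([xn[0], xn[1], 1.0])
        d = d / np.linalg.norm(d)
        P = np.eye(3) - np.outer(d, d)
        A.append(P)
        b.append(P @ c)
    return np.linalg.lstsq(np.vstack(A), np.concatenate(b), rcond=None)[0]


class TestFusion:
    def test_all_zero_inputs_give_identity(self):
        fused = fuse_pose(Pose6DOF(), 0.0, 0.0, 0.0)
        assert fused.valid
        assert np.allclose(fused.pose.as_array(), 0.0)
        assert fused.methods == {"x": "PnP", "y": "PnP", "roll": "PnP",
                                 "z": "DLT", "pitch": "moire", "yaw": "moire"}

    def test_division_of_labour(self):
        pnp = Pose6DOF(0.3, -0.2, 99.0, 99.0, 99.0, 1.0)  # through-plane PnP junk
        fused = fuse_pose(pnp, 0.5, 0.4, -0.6)
        assert fused.pose.tz == 0.5
        assert fused.pose.pitch == 0.4
        assert fused.pose.yaw == -0.6
        assert (fused.pose.tx, fused.pose.ty, fused.pose.roll) == (0.3, -0.2, 1.0)

    def test_missing_component_invalidates_frame(self):
        fused = fuse_pose(Pose6DOF(0.3, -0.2, 0, 0, 0, 1.0), 0.5, None, -0.6)
        assert not fused.valid
        assert "pitch" not in fused.methods
        assert fused.pose is not None  # partial PnP record retained


class TestTraceAndFilter:
    def test_trace_requires_increasing_timestamps(self):
        with pytest.raises(ValueError):
            PoseTrace.from_arrays([0.0, 0.0], np.zeros((2, 6)))

    def test_invalid_frames_carry_no_pose(self):
        trace = PoseTrace.from_arrays([0, 1 / 30], np.ones((2, 6)),
                                      valid=[True, False])
        assert np.isnan(trace.dof_array[1]).all()
        assert not np.isnan(trace.dof_array[0]).any()

    def test_lowpass_attenuates_above_cutoff(self):
        # white noise trace: power above 5 Hz must drop by > 20 dB
        rng = np.random.default_rng(0)
        n, fs = 512, 30.0
        dof = rng.normal(0, 1, (n, 6))
        trace = PoseTrace.from_arrays(np.arange(n) / fs, dof)
        filt = lowpass_trace(trace, 5.0)
        f = np.fft.rfftfreq(n, 1 / fs)
        for j in range(6):
            before = np.abs(np.fft.rfft(dof[:, j]))
            after = np.abs(np.fft.rfft(filt.dof_array[:, j]))
            hi = f > 6.0
            ratio = np.sum(after[hi] ** 2) / np.sum(before[hi] ** 2)
            assert 10 * np.log10(max(ratio, 1e-30)) < -20

    def test_lowpass_preserves_slow_component(self):
        n, fs = 300, 30.0  # 1 Hz sits exactly on a frequency bin
        t = np.arange(n) / fs
        dof = np.outer(np.sin(2 * np.pi * 1.0 * t), np.ones(6))
        filt = lowpass_trace(PoseTrace.from_arrays(t, dof), 5.0)
        assert np.allclose(filt.dof_array, dof, atol=1e-10)


class TestTrackSequence:
    def test_short_static_and_stepped_sequence(self, spec, stereo):
        rig, camL, camR = stereo
        rng = np.random.default_rng(9)
        opts = RenderOptions(noise_sigma=1.0)
        base = Pose6DOF(tx=0.1, ty=-0.2, roll=0.3)
        stepped = pose_offset(base, yaw=0.1, tz=0.2)
        lf, rf = [], []
        poses = [base, base, stepped, stepped]
        for i, p in enumerate(poses):
            lf.append(render_marker_view(p, camL, spec, opts, rng=rng, timestamp=i / 30))
            rf.append(render_marker_view(p, camR, spec, opts, rng=rng, timestamp=i / 30))
        trace = track_sequence(lf, rf, spec, rig, lowpass_hz=None,
                               world_to_left=camL.world_to_cam)
        assert len(trace) == 4
        assert trace.valid.all()
        dof = trace.dof_array
        assert np.allclose(dof[0], 0.0, atol=0.03)
        assert dof[2, 4] == pytest.approx(0.1, abs=0.03)   # yaw step
        assert dof[2, 2] == pytest.approx(0.2, abs=0.05)   # z step
        assert abs(dof[2, 0]) < 0.05 and abs(dof[2, 5]) < 0.05

    def test_occluded_frame_flagged_not_interpolated(self, spec, stereo):
        rig, camL, camR = stereo
        base = Pose6DOF(tx=0.1, ty=-0.2, roll=0.3)
        opts = RenderOptions()
        occl = RenderOptions(occlusions=[(0, 0, 720, 240, 90.0)])
        lf = [render_marker_view(base, camL, spec, o, timestamp=i / 30)
              for i, o in enumerate([opts, occl, opts])]
        rf = [render_marker_view(base, camR, spec, opts, timestamp=i / 30)
              for i in range(3)]
        trace = track_sequence(lf, rf, spec, rig, lowpass_hz=None,
                               world_to_left=camL.world_to_cam)
        assert list(trace.valid) == [True, False, True]
        assert np.isnan(trace.dof_array[1]).all()

    def test_occluded_reference_raises(self, spec, stereo):
        from moiretrack.detection import OcclusionError

        rig, camL, camR = stereo
        base = Pose6DOF()
        occl = RenderOptions(occlusions=[(0, 0, 720, 240, 90.0)])
        lf = [render_marker_view(base, camL, spec, occl, timestamp=0.0)]
        rf = [render_marker_view(base, camR, spec, RenderOptions(), timestamp=0.0)]
        with pytest.raises(OcclusionError):
            track_sequence(lf, rf, spec, rig, lowpass_hz=None)
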