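"""6-DOF marker pose estimation.

Division of labour across methods, matching the marker design:

* in-plane translation (X, Y) and roll -- planar PnP on the checkerboard
  corners of a single (left) camera;
* depth (Z) -- DLT triangulation of the checkerboard corners across the
  stereo pair, reported as displacement of the corner centroid along the
  left camera's optical axis;
* pitch and yaw -- moiré phase analysis (see :mod:`moiretrack.detection`).

Monocular PnP does return all six DOF, but with the narrow-field cameras
used here (~1.5 degree FOV) its through-plane components are unstable, which
is why only tx/ty/roll are flagged reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.transform import Rotation

from .geometry import Pose6DOF, RigidTransform
from .marker import MarkerSpec

__all__ = [
    "CameraIntrinsics",
    "StereoRig",
    "PnPResult",
    "PoseTrace",
    "solve_planar_pnp",
    "solve_inplane_pnp",
    "triangulate_points",
    "fuse_pose",
    "track_sequence",
    "lowpass_trace",
]


# ---------------------------------------------------------------------------
# Camera models
# ---------------------------------------------------------------------------

@dataclass
class CameraIntrinsics:
    """Pinhole camera with radial-tangential distortion (k1, k2, p1, p2, k3)."""

    fx: float
    fy: float
    cx: float
    cy: float
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))
    resolution: tuple[int, int] = (720, 480)  # (width, height)

    def __post_init__(self) -> None:
        self.distortion = np.asarray(self.distortion, dtype=float).reshape(-1)
        if self.distortion.size < 5:
            self.distortion = np.pad(self.distortion, (0, 5 - self.distortion.size))
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        w, h = self.resolution
        if not (0 <= self.cx <= w and 0 <= self.cy <= h):
            raise ValueError("principal point outside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0, self.cx], [0, self.fy, self.cy], [0, 0, 1.0]])

    def _distort_normalized(self, xn: np.ndarray) -> np.ndarray:
        k1, k2, p1, p2, k3 = self.distortion
        x, y = xn[:, 0], xn[:, 1]
        r2 = x * x + y * y
        radial = 1 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
        xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        return np.column_stack([xd, yd])

    def project(self, points_cam: np.ndarray) -> np.ndarray:
        """Project camera-frame 3-D points (mm) to pixel coordinates."""
        p = np.atleast_2d(np.asarray(points_cam, dtype=float))
        z = p[:, 2]
        if np.any(z <= 0):
            raise ValueError("points behind the camera")
        xn = p[:, :2] / z[:, None]
        xd = self._distort_normalized(xn)
        return np.column_stack([self.fx * xd[:, 0] + self.cx,
                                self.fy * xd[:, 1] + self.cy])

    def undistort_points(self, px: np.ndarray, iterations: int = 8) -> np.ndarray:
        """Pixel coordinates -> undistorted normalized image coordinates."""
        px = np.atleast_2d(np.asarray(px, dtype=float))
        xd = np.column_stack([(px[:, 0] - self.cx) / self.fx,
                              (px[:, 1] - self.cy) / self.fy])
        if not self.distortion.any():
            return xd
        xn = xd.copy()
        for _ in range(iterations):  # fixed-point inversion of the distortion map
            delta = self._distort_normalized(xn) - xn
            xn = xd - delta
        return xn

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                "distortion": self.distortion.tolist(),
                "resolution": list(self.resolution)}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                   distortion=np.asarray(d.get("distortion", np.zeros(5))),
                   resolution=tuple(d.get("resolution", (720, 480))))


@dataclass
class StereoRig:
    """Calibrated stereo pair; ``extrinsic`` maps right-camera to left-camera coordinates."""

    left: CameraIntrinsics
    right: CameraIntrinsics
    extrinsic: RigidTransform

    def __post_init__(self) -> None:
        if np.linalg.norm(self.extrinsic.translation) <= 0:
            raise ValueError("stereo rig requires a non-zero baseline")

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.extrinsic.translation))

    def projection_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(P_left, P_right) mapping homogeneous left-frame points to pixels."""
        P_l = self.left.K @ np.hstack([np.eye(3), np.zeros((3, 1))])
        inv = self.extrinsic.inverse()  # left -> right
        P_r = self.right.K @ np.hstack([inv.rotation, inv.translation[:, None]])
        return P_l, P_r


# ---------------------------------------------------------------------------
# Planar PnP
# ---------------------------------------------------------------------------

def _homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping src (N,2) to dst (N,2)."""

    def normalise(p):
        c = p.mean(axis=0)
        s = np.sqrt(2) / max(np.mean(np.linalg.norm(p - c, axis=1)), 1e-12)
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        ph = np.column_stack([p, np.ones(len(p))]) @ T.T
        return ph, T

    sh, Ts = normalise(src)
    dh, Td = normalise(dst)
    A = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(A))
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


@dataclass
class PnPResult:
    """Marker-to-camera pose from planar PnP with reliability bookkeeping."""

    transform: RigidTransform      # marker frame -> camera frame
    pose: Pose6DOF                 # Euler decomposition of ``transform``
    reprojection_rms: float        # px
    reliable: tuple[str, ...] = ("tx", "ty", "roll")


def solve_planar_pnp(object_xy: np.ndarray, image_px: np.ndarray,
                     intrinsics: CameraIntrinsics, refine: bool = True) -> PnPResult:
    """Pose of a planar target (z=0 object points, mm) from one camera view.

    Initialised from the plane-to-image homography decomposition and refined
    by Levenberg-Marquardt on the pixel reprojection error.
    """
    obj = np.asarray(object_xy, dtype=float)
    px = np.asarray(image_px, dtype=float)
    if obj.shape[0] < 6 or obj.shape[0] != px.shape[0]:
        raise ValueError("need >= 6 matched correspondences")
    xn = intrinsics.undistort_points(px)
    H = _homography(obj, xn)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 2.0 / (np.linalg.norm(h1) + np.linalg.norm(h2))
    if h3[2] * lam < 0:  # target must be in front of the camera
        lam = -lam
    r1, r2, t = lam * h1, lam * h2, lam * h3
    R_approx = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(R_approx)
    R = u @ np.diag([1, 1, np.linalg.det(u @ vt)]) @ vt
    if t[2] < 0:
        raise ValueError("degenerate PnP configuration (target behind camera)")

    obj3 = np.column_stack([obj, np.zeros(len(obj))])

    def residual(p):
        Rp = Rotation.from_rotvec(p[:3]).as_matrix()
        cam = obj3 @ Rp.T + p[3:]
        return (intrinsics.project(cam) - px).ravel()

    p0 = np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
    if refine:
        res = optimize.least_squares(residual, p0, method="lm", xtol=1e-12, ftol=1e-12)
        if not np.all(np.isfinite(res.x)):
            raise ValueError("PnP refinement diverged")
        p = res.x
    else:
        p = p0
    T = RigidTransform(rotation=Rotation.from_rotvec(p[:3]).as_matrix(), translation=p[3:])
    rms = float(np.sqrt(np.mean(residual(p) ** 2)))
    return PnPResult(transform=T, pose=T.to_pose(frame_id="camera"), reprojection_rms=rms)


def solve_inplane_pnp(corners_px: np.ndarray, intrinsics: CameraIntrinsics,
                      spec: MarkerSpec) -> PnPResult:
    """Planar PnP on the marker's checkerboard corners.

    The full 6-DOF solution is returned but only the in-plane components
    (tx, ty, roll) are flagged reliable; through-plane PnP components are
    unstable at a ~1.5 degree field of view.
    """
    return solve_planar_pnp(spec.checkerboard_inner_corners(), corners_px, intrinsics)


# ---------------------------------------------------------------------------
# Stereo triangulation (DLT)
# ---------------------------------------------------------------------------

def triangulate_points(left_px: np.ndarray, right_px: np.ndarray, rig: StereoRig,
                       min_ray_angle_deg: float = 0.05) -> np.ndarray:
    """DLT triangulation of matched pixel points into left-camera-frame mm.

    Points are undistorted first; rays closer to parallel than
    ``min_ray_angle_deg`` raise a conditioning error.
    """
    lp = np.atleast_2d(np.asarray(left_px, dtype=float))
    rp = np.atleast_2d(np.asarray(right_px, dtype=float))
    if lp.shape != rp.shape:
        raise ValueError("left/right correspondence counts differ")
    ln = rig.left.undistort_points(lp)
    rn = rig.right.undistort_points(rp)

    # ray-parallelism check in the left frame
    d_l = np.column_stack([ln, np.ones(len(ln))])
    d_l /= np.linalg.norm(d_l, axis=1, keepdims=True)
    d_r = np.column_stack([rn, np.ones(len(rn))]) @ rig.extrinsic.rotation.T
    d_r /= np.linalg.norm(d_r, axis=1, keepdims=True)
    cosang = np.abs(np.sum(d_l * d_r, axis=1))
    if np.any(cosang > np.cos(np.radians(min_ray_angle_deg))):
        raise ValueError("near-parallel rays: triangulation ill-conditioned")

    # ideal (undistorted) projection matrices
    P_l = np.hstack([np.eye(3), np.zeros((3, 1))])
    inv = rig.extrinsic.inverse()
    P_r = np.hstack([inv.rotation, inv.translation[:, None]])
    out = np.empty((len(ln), 3))
    for i, ((xl, yl), (xr, yr)) in enumerate(zip(ln, rn)):
        A = np.stack([
            xl * P_l[2] - P_l[0],
            yl * P_l[2] - P_l[1],
            xr * P_r[2] - P_r[0],
            yr * P_r[2] - P_r[1],
        ])
        _, _, vt = np.linalg.svd(A)
        X = vt[-1]
        out[i] = X[:3] / X[3]
    return out


# ---------------------------------------------------------------------------
# Fusion and tracking
# ---------------------------------------------------------------------------

@dataclass
class FusedPose:
    pose: Pose6DOF | None
    valid: bool
    methods: dict[str, str] = field(default_factory=dict)


def fuse_pose(pnp: Pose6DOF | None, z_dlt: float | None,
              pitch_moire: float | None, yaw_moire: float | None) -> FusedPose:
    """Combine the per-method DOF estimates for one frame.

    tx/ty/roll from PnP, tz from DLT, pitch/yaw from moiré.  Any missing
    component invalidates the frame; a partial record (with method tags for
    whatever was available) is still returned for bookkeeping.
    """
    methods = {}
    if pnp is not None:
        methods.update({"x": "PnP", "y": "PnP", "roll": "PnP"})
    if z_dlt is not None:
        methods["z"] = "DLT"
    if pitch_moire is not None:
        methods["pitch"] = "moire"
    if yaw_moire is not None:
        methods["yaw"] = "moire"
    if pnp is None or z_dlt is None or pitch_moire is None or yaw_moire is None:
        partial = None
        if pnp is not None:
            partial = Pose6DOF(pnp.tx, pnp.ty, 0.0, 0.0, 0.0, pnp.roll,
                               frame_id=pnp.frame_id)
        return FusedPose(pose=partial, valid=False, methods=methods)
    fused = Pose6DOF(pnp.tx, pnp.ty, float(z_dlt), float(pitch_moire),
                     float(yaw_moire), pnp.roll, frame_id=pnp.frame_id)
    return FusedPose(pose=fused, valid=True, methods=methods)


TRACE_COLUMNS = ["frame_index", "time_s", "x_mm", "y_mm", "z_mm",
                 "pitch_deg", "yaw_deg", "roll_deg", "valid", "methods"]


@dataclass
class PoseTrace:
    """Time-stamped 6-DOF pose sequence with validity flags."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace missing columns {missing}")
        t = self.data["time_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trace timestamps must be strictly increasing")
        invalid = ~self.data["valid"].to_numpy(dtype=bool)
        dof = self.data[["x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg", "roll_deg"]]
        if invalid.any() and not dof[invalid].isna().all(axis=None):
            # invalid frames carry no pose values
            self.data.loc[invalid, dof.columns] = np.nan

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dof_array(self) -> np.ndarray:
        """(N, 6) array of [x, y, z, pitch, yaw, roll]; NaN on invalid frames."""
        return self.data[["x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg",
                          "roll_deg"]].to_numpy(dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return self.data["valid"].to_numpy(dtype=bool)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    def poses(self) -> list[Pose6DOF | None]:
        out = []
        for row, ok in zip(self.dof_array, self.valid):
            out.append(Pose6DOF.from_array(row, frame_id="reference") if ok else None)
        return out

    @classmethod
    def from_arrays(cls, times: np.ndarray, dof: np.ndarray,
                    valid: np.ndarray | None = None,
                    methods: list[str] | None = None) -> "PoseTrace":
        times = np.asarray(times, dtype=float)
        dof = np.asarray(dof, dtype=float)
        n = len(times)
        if valid is None:
            valid = np.ones(n, dtype=bool)
        if methods is None:
            methods = [""] * n
        df = pd.DataFrame({
            "frame_index": np.arange(n),
            "time_s": times,
            "x_mm": dof[:, 0], "y_mm": dof[:, 1], "z_mm": dof[:, 2],
            "pitch_deg": dof[:, 3], "yaw_deg": dof[:, 4], "roll_deg": dof[:, 5],
            "valid": np.asarray(valid, dtype=bool),
            "methods": methods,
        })
        return cls(df)


def lowpass_trace(trace: PoseTrace, cutoff_hz: float) -> PoseTrace:
    """Zero-phase frequency-domain low-pass of each DOF.

    A hard spectral mask is applied independently to every maximal run of
    valid frames (invalid frames are never interpolated across).  The cutoff
    defaults elsewhere to 5 Hz -- above the simulator's 2.3 Hz upper bound of
    physiological motion, suppressing camera/wall vibration bands.
    """
    df = trace.data.copy()
    valid = trace.valid
    t = trace.times
    dof = trace.dof_array.copy()
    idx = np.flatnonzero(valid)
    if idx.size:
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) < 4:
                continue
            fs = 1.0 / np.median(np.diff(t[run]))
            freqs = np.fft.rfftfreq(len(run), d=1.0 / fs)
            mask = freqs <= cutoff_hz
            seg = dof[run]
            spec = np.fft.rfft(seg, axis=0)
            spec[~mask] = 0.0
            dof[run] = np.fft.irfft(spec, n=len(run), axis=0)
    df[["x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg", "roll_deg"]] = dof
    return PoseTrace(df)


def _match_stereo_frames(left_frames, right_frames, tolerance_s: float):
    """Nearest-timestamp pairing; unmatched frames are dropped."""
    rt = np.array([f.timestamp for f in right_frames])
    pairs = []
    for i, lf in enumerate(left_frames):
        j = int(np.argmin(np.abs(rt - lf.timestamp)))
        if abs(rt[j] - lf.timestamp) <= tolerance_s:
            pairs.append((i, j))
    return pairs


def track_sequence(left_frames, right_frames, spec: MarkerSpec, rig: StereoRig,
                   reference_frame: int = 0, lowpass_hz: float | None = 5.0,
                   world_to_left: RigidTransform | None = None,
                   pair_tolerance_s: float = 1.0 / 60.0,
                   phase_signs: dict[str, float] | None = None,
                   px_per_mm: float = 8.0, refine_corners: bool = False) -> PoseTrace:
    """Track the marker through paired stereo streams, relative to a reference frame.

    Per matched frame pair: anchor detection and rectification, checkerboard
    corners predicted through the marker homography (the anchor corners are
    sub-pixel line-fit intersections, so the homography localises the board
    corners more precisely than per-corner saddle refinement; set
    ``refine_corners`` to add the saddle iteration), planar PnP (left
    camera), DLT depth of the corner centroid, moiré pitch/yaw, all
    differenced against the reference frame.  Occluded frames are flagged
    invalid, never interpolated.

    ``world_to_left`` is the left camera's placement (world-to-camera); when
    given, increments are reported in the world/marker frame (X right, Y up,
    Z toward the cameras).  Without it they remain in left-camera axes.
    """
    from .detection import (analyse_frame, rotations_from_analysis, detect_aruco,
                            marker_homography, OcclusionError)
    from .corners import refine_checkerboard_corners

    pairs = _match_stereo_frames(left_frames, right_frames, pair_tolerance_s)
    if not pairs:
        raise ValueError("no stereo frame pairs within the pairing tolerance")

    obj = spec.checkerboard_inner_corners()
    cam_to_world = world_to_left.inverse() if world_to_left is not None else None

    def measure(li, ri):
        lf, rf = left_frames[li], right_frames[ri]
        analysis = analyse_frame(lf, spec, px_per_mm=px_per_mm)
        if analysis.occluded:
            return None
        corners_l = analysis.rectified.transform(obj)
        pnp = solve_inplane_pnp(corners_l, rig.left, spec)
        dets_r = detect_aruco(rf, spec)
        if len(dets_r) < 4:
            return None
        corners_r = marker_homography(dets_r, spec)(obj)
        if refine_corners:
            corners_l = refine_checkerboard_corners(lf.pixels, corners_l)
            corners_r = refine_checkerboard_corners(rf.pixels, corners_r)
        pts3 = triangulate_points(corners_l, corners_r, rig)
        if cam_to_world is not None:
            marker_pose = (cam_to_world @ pnp.transform).to_pose(frame_id="world")
        else:
            marker_pose = pnp.pose
        return analysis, marker_pose, float(pts3.mean(axis=0)[2])

    ref = measure(*pairs[reference_frame])
    if ref is None:
        raise OcclusionError("reference frame is occluded")
    ref_analysis, ref_pose, ref_z = ref
    # sign of a left-camera optical-axis displacement expressed on the world Z axis
    z_axis_gain = float(cam_to_world.rotation[2, 2]) if cam_to_world is not None else 1.0

    times, dof_rows, valids, methods = [], [], [], []
    for k, (li, ri) in enumerate(pairs):
        times.append(left_frames[li].timestamp)
        m = ref if k == reference_frame else measure(li, ri)
        if m is None:
            dof_rows.append([np.nan] * 6)
            valids.append(False)
            methods.append("")
            continue
        analysis, marker_pose, z = m
        rel = marker_pose - ref_pose
        rot = rotations_from_analysis(analysis, ref_analysis, spec,
                                      phase_signs=phase_signs)
        fused = fuse_pose(rel, z_axis_gain * (z - ref_z), rot["pitch"], rot["yaw"])
        dof_rows.append(fused.pose.as_array() if fused.valid else [np.nan] * 6)
        valids.append(fused.valid)
        methods.append("|".join(f"{k2}:{v}" for k2, v in sorted(fused.methods.items())))

    trace = PoseTrace.from_arrays(np.asarray(times), np.asarray(dof_rows),
                                  np.asarray(valids), methods)
    if lowpass_hz is not None and len(trace) > 8:
        trace = lowpass_trace(trace, lowpass_hz)
    return trace
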