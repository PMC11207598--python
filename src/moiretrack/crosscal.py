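"""Camera-to-MRI cross-calibration.

The rigid transform between the optical-tracking frame and the MRI frame is
solved from matched point pairs (camera-visible ArUco squares paired with
MRI-visible fluid wells on a phantom) by the Kabsch/Umeyama SVD method,
after a documented preprocessing chain that removes the large, approximately
known frame differences first:

1. mirror fold: -90 deg rotation about X (the phantom is viewed via the
   head-coil mirror);
2. frame convention: 180 deg rotations about X and then Z (camera vs MRI
   axis conventions);
3. gross offset: -3000 mm translation in Z (camera-to-isocentre distance).

Removing these first limits rounding error in the SVD solve, leaving only a
small residual transform to estimate.  Each step can be toggled off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Pose6DOF, RigidTransform

__all__ = [
    "PointCorrespondences",
    "PhantomSpec",
    "preprocessing_transform",
    "preprocess_camera_points",
    "solve_rigid_transform",
    "apply_transform",
    "repeatability",
]

DOF_NAMES = ["x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg", "roll_deg"]


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    p = points - points.mean(axis=0)
    s = np.linalg.svd(p, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


@dataclass
class PointCorrespondences:
    """Matched source (camera-frame) and target (MRI-frame) points in mm."""

    source: np.ndarray
    target: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if self.source.shape != self.target.shape:
            raise ValueError("source/target point counts differ")
        if len(self.source) < 3:
            raise ValueError("need at least 3 point pairs")
        if not self.labels:
            self.labels = list(range(len(self.source)))
        if len(self.labels) != len(self.source):
            raise ValueError("label count does not match point count")
        if _collinear(self.source) or _collinear(self.target):
            raise ValueError("point set is collinear; the rotation is unconstrained")

    def subset(self, labels) -> "PointCorrespondences":
        idx = [self.labels.index(l) for l in labels]
        return PointCorrespondences(self.source[idx], self.target[idx], list(labels))


@dataclass
class PhantomSpec:
    """The 15-point cross-calibration phantom.

    15 vertical fluid-filled wells (MRI-visible) arranged in a 3 x 5 grid,
    each paired with an ArUco square (camera-visible) directly above it at a
    known depth offset.
    """

    grid_shape: tuple[int, int] = (3, 5)
    spacing_mm: tuple[float, float] = (30.0, 25.0)
    well_depths_mm: tuple = (0.0, 5.0, 10.0, 15.0, 20.0)  # per column, staggered
    aruco_face_mm: float = 25.0   # ArUco squares sit on the top face

    def well_positions(self) -> np.ndarray:
        """Well points in the phantom frame (mm).

        Wells are drilled to staggered depths column by column: the depth
        variation takes the point set out of a single plane, which conditions
        the rotation estimate much better than a flat grid.
        """
        nr, nc = self.grid_shape
        sx, sy = self.spacing_mm
        xs = (np.arange(nc) - (nc - 1) / 2) * sx
        ys = (np.arange(nr) - (nr - 1) / 2) * sy
        gx, gy = np.meshgrid(xs, ys)
        gz = -np.broadcast_to(np.asarray(self.well_depths_mm), (nr, nc))
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def aruco_positions(self) -> np.ndarray:
        pts = self.well_positions().copy()
        pts[:, 2] = self.aruco_face_mm
        return pts

    def depth_offsets(self) -> np.ndarray:
        """Per-pair vertical distance between an ArUco square and its well point."""
        return self.aruco_positions()[:, 2] - self.well_positions()[:, 2]

    def n_points(self) -> int:
        return int(np.prod(self.grid_shape))


def preprocessing_transform(mirror_fold: bool = True, frame_convention: bool = True,
                            z_offset: bool = True,
                            z_offset_mm: float = -3000.0) -> RigidTransform:
    """The fixed preprocessing applied to raw camera points before the SVD solve.

    Order: mirror fold (-90 deg about X), then the 180 deg X and Z
    frame-convention rotations, then the gross Z translation.
    """
    T = RigidTransform.identity()
    if mirror_fold:
        T = RigidTransform.rotation_about("x", -90.0) @ T
    if frame_convention:
        T = RigidTransform.rotation_about("z", 180.0) @ RigidTransform.rotation_about("x", 180.0) @ T
    if z_offset:
        T = RigidTransform(translation=[0, 0, z_offset_mm]) @ T
    return T


def preprocess_camera_points(points: np.ndarray, mirror_fold: bool = True,
                             frame_convention: bool = True, z_offset: bool = True,
                             z_offset_mm: float = -3000.0) -> np.ndarray:
    """Apply the preprocessing chain to raw camera-frame points."""
    T = preprocessing_transform(mirror_fold, frame_convention, z_offset, z_offset_mm)
    return T.apply(np.asarray(points, dtype=float))


def solve_rigid_transform(corr: PointCorrespondences) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform target = R @ source + t (Kabsch, no scaling).

    Returns the transform and the fiducial registration error, defined here
    as the RMS of the residual pair distances after alignment.
    """
    src, dst = corr.source, corr.target
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    u, s, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - R @ cs
    T = RigidTransform(rotation=R, translation=t)
    residual = T.apply(src) - dst
    fre = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    return T, fre


def apply_transform(T: RigidTransform, x):
    """Rigid action of ``T`` on points (N, 3), a Pose6DOF, or another transform."""
    if isinstance(x, RigidTransform):
        return T @ x
    if isinstance(x, Pose6DOF):
        return (T @ x.to_transform()).to_pose(frame_id=x.frame_id)
    return T.apply(np.asarray(x, dtype=float))


def repeatability(trials: list[RigidTransform]) -> pd.DataFrame:
    """Per-DOF spread across repeated cross-calibration solutions.

    Each trial transform is decomposed into 6 DOF; the table reports the
    mean, standard deviation and the maximum absolute deviation from the
    mean for each DOF (the repeatability metric used to accept the
    procedure: all max deviations below 1 mm / 1 deg).
    """
    if len(trials) < 2:
        raise ValueError("repeatability needs at least 2 trials")
    rows = np.stack([t.to_pose().as_array() for t in trials])
    mean = rows.mean(axis=0)
    dev = np.abs(rows - mean)
    return pd.DataFrame({
        "mean": mean,
        "sd": rows.std(axis=0, ddof=1),
        "max_deviation": dev.max(axis=0),
    }, index=DOF_NAMES)
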