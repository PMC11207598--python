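"""Rigid-body geometry shared across the tracking pipeline.

Conventions
-----------
* All 6-DOF poses are (tx, ty, tz) in millimetres and (pitch, yaw, roll) in
  degrees: pitch about X, yaw about Y, roll about Z.
* Rotation matrices are built from Euler angles with intrinsic rotations
  applied in the order roll(Z) . yaw(Y) . pitch(X).  At the <= 2 degree
  amplitudes relevant to head tracking the ordering effect is < 0.01 deg, but
  the convention is fixed so that every module decomposes rotations the same
  way.
* The marker frame has X right, Y up and Z out of the marker face toward the
  cameras.  Camera frames are pinhole-style: X right, Y down, Z along the
  optical axis into the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose6DOF",
    "RigidTransform",
    "euler_to_matrix",
    "matrix_to_euler",
    "look_at",
]

#: scipy Euler sequence implementing intrinsic Rz(roll) @ Ry(yaw) @ Rx(pitch)
EULER_SEQ = "ZYX"


def euler_to_matrix(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Rotation matrix for intrinsic Z(roll)-Y(yaw)-X(pitch) Euler angles in degrees."""
    return Rotation.from_euler(EULER_SEQ, [roll, yaw, pitch], degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; returns (pitch, yaw, roll) in degrees."""
    roll, yaw, pitch = Rotation.from_matrix(R).as_euler(EULER_SEQ, degrees=True)
    return float(pitch), float(yaw), float(roll)


@dataclass
class Pose6DOF:
    """A 6-DOF pose: translations in mm, rotations in degrees.

    ``frame_id`` labels the coordinate frame the pose is expressed in
    (e.g. ``"world"``, ``"camera:left"``, ``"reference"``).
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0
    frame_id: str = "world"

    def __post_init__(self) -> None:
        vals = [self.tx, self.ty, self.tz, self.pitch, self.yaw, self.roll]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"Pose6DOF requires finite components, got {vals}")

    def as_array(self) -> np.ndarray:
        """(tx, ty, tz, pitch, yaw, roll) as a float array."""
        return np.array(
            [self.tx, self.ty, self.tz, self.pitch, self.yaw, self.roll], dtype=float
        )

    @classmethod
    def from_array(cls, a, frame_id: str = "world") -> "Pose6DOF":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError(f"expected 6 components, got shape {a.shape}")
        return cls(*a, frame_id=frame_id)

    def to_transform(self) -> "RigidTransform":
        return RigidTransform(
            rotation=euler_to_matrix(self.pitch, self.yaw, self.roll),
            translation=np.array([self.tx, self.ty, self.tz], dtype=float),
        )

    def __sub__(self, other: "Pose6DOF") -> "Pose6DOF":
        """Componentwise pose difference (valid in the small-angle regime)."""
        return Pose6DOF.from_array(self.as_array() - other.as_array(), frame_id=self.frame_id)


@dataclass
class RigidTransform:
    """Rotation + translation, acting as ``x -> R @ x + t`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (|R'R - I|max = {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det = -1 (reflection)")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    @classmethod
    def from_euler(cls, pitch: float = 0.0, yaw: float = 0.0, roll: float = 0.0,
                   translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(rotation=euler_to_matrix(pitch, yaw, roll),
                   translation=np.asarray(translation, dtype=float))

    @classmethod
    def rotation_about(cls, axis: str, angle_deg: float) -> "RigidTransform":
        """Pure rotation about one of the frame axes 'x', 'y' or 'z'."""
        return cls(rotation=Rotation.from_euler(axis.lower(), angle_deg, degrees=True).as_matrix())

    # -- group operations ---------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (N, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(rotation=self.rotation.T,
                              translation=-self.rotation.T @ self.translation)

    # -- views ---------------------------------------------------------
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_pose(self, frame_id: str = "world") -> Pose6DOF:
        pitch, yaw, roll = matrix_to_euler(self.rotation)
        tx, ty, tz = self.translation
        return Pose6DOF(tx, ty, tz, pitch, yaw, roll, frame_id=frame_id)


def look_at(camera_center: np.ndarray, target: np.ndarray,
            up=(0.0, 1.0, 0.0)) -> RigidTransform:
    """World-to-camera transform for a camera at ``camera_center`` looking at ``target``.

    The camera Z axis points from the centre toward the target and the camera
    Y axis points opposite the world ``up`` direction (image rows grow
    downward).
    """
    c = np.asarray(camera_center, dtype=float)
    fwd = np.asarray(target, dtype=float) - c
    n = np.linalg.norm(fwd)
    if n == 0:
        raise ValueError("camera centre and target coincide")
    z = fwd / n
    down = -np.asarray(up, dtype=float)
    y = down - np.dot(down, z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise ValueError("up direction is parallel to the viewing direction")
    y = y / ny
    x = np.cross(y, z)
    R = np.stack([x, y, z])  # rows are camera axes in world coordinates
    return RigidTransform(rotation=R, translation=-R @ c)
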