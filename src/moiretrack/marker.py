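"""Physical model of the moiré-enhanced fiducial marker.

The marker is a flat face carrying

* a central checkerboard, tracked via planar PnP (in-plane X/Y/roll) and
  stereo triangulation (depth Z);
* four ArUco anchor squares in the corners, used to localise and rectify the
  marker before moiré analysis;
* four moiré grating pairs (a fine and a coarse pair for each of pitch and
  yaw) that convert small through-plane rotations into large phase shifts of
  a low-frequency beat pattern.

Moiré rotation <-> phase model
------------------------------
Each grating pair consists of two line prints with slightly different spatial
frequencies, laminated to the two sides of a transparent substrate of
thickness ``d`` and refractive index ``n``.  A through-plane rotation
``theta`` tilts the viewing ray, which refracts through the substrate and
samples the far grating layer at a laterally shifted position; the beat
pattern formed by the superposed prints shifts in phase by ``phi`` with

    theta = n * sin(atan(phi / (2 * pi * f1 * d)))

where ``f1`` is the spatial frequency of the higher-frequency print
(lines/mm).  The model is exact when the higher-frequency print is the layer
on the far side of the substrate from the viewer (the beat phase produced by
a lateral shift ``delta`` of the far layer is ``2*pi*f_far*delta``); the
synthetic renderer lays the prints out that way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import Pose6DOF  # noqa: F401  (re-exported: Pose6DOF is part of the marker model)

__all__ = [
    "MoireGratingPair",
    "MarkerSpec",
    "ArucoAnchor",
    "Pose6DOF",
    "rotation_from_phase",
    "phase_from_rotation",
    "phase_wrap_rotation",
    "aruco_dictionary",
    "default_marker_spec",
]

#: refractive index of polycarbonate, used when a marker spec does not override it
DEFAULT_REFRACTIVE_INDEX = 1.585


@dataclass
class MoireGratingPair:
    """One moiré grating pair and the substrate it is printed on.

    Parameters
    ----------
    f_front, f_back:
        Spatial frequencies of the two prints in lines/mm, ``f_front`` being
        the higher frequency (the Eq.-model symbol f1).  The renderer places
        the ``f_front`` print on the far side of the substrate so the
        rotation/phase model is exact.
    d:
        Layer separation (substrate thickness), mm.
    n_refractive:
        Substrate refractive index (>= 1).
    axis:
        Which through-plane rotation the pair senses: ``"pitch"`` (about X,
        line frequency along Y) or ``"yaw"`` (about Y, line frequency along X).
    grade:
        ``"fine"`` or ``"coarse"``; the coarse pair has the larger phase-wrap
        rotation and disambiguates the fine pair's wrap count.
    region:
        ``(x0, y0, x1, y1)`` rectangle on the marker face in mm, marker frame.
    """

    f_front: float
    f_back: float
    d: float = 10.0
    n_refractive: float = DEFAULT_REFRACTIVE_INDEX
    axis: str = "yaw"
    grade: str = "fine"
    region: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.f_front > self.f_back > 0):
            raise ValueError(
                f"require f_front > f_back > 0, got {self.f_front}, {self.f_back}")
        if self.d <= 0:
            raise ValueError("substrate thickness d must be positive")
        if self.n_refractive < 1:
            raise ValueError("refractive index must be >= 1")
        if self.axis not in ("pitch", "yaw"):
            raise ValueError(f"axis must be 'pitch' or 'yaw', got {self.axis!r}")
        if self.grade not in ("fine", "coarse"):
            raise ValueError(f"grade must be 'fine' or 'coarse', got {self.grade!r}")
        x0, y0, x1, y1 = self.region
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate grating region {self.region}")

    @property
    def beat_frequency(self) -> float:
        """Beat frequency of the superposed prints, lines/mm."""
        return self.f_front - self.f_back

    @property
    def profile_axis(self) -> str:
        """Axis along which the line frequency (and the 1-D profile) runs."""
        return "x" if self.axis == "yaw" else "y"


def rotation_from_phase(phase: float, grating: MoireGratingPair) -> float:
    """Physical through-plane rotation (degrees) for a moiré phase shift (radians).

    Odd and strictly increasing in ``phase``.  ``phase`` is the shift of the
    beat pattern relative to the reference orientation; one full cycle
    (``2*pi``) corresponds to the pair's phase-wrap rotation.
    """
    phase = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase must be finite")
    x = phase / (2.0 * np.pi * grating.f_front * grating.d)
    theta_rad = grating.n_refractive * np.sin(np.arctan(x))
    return np.degrees(theta_rad) if phase.ndim else float(np.degrees(theta_rad))


def phase_from_rotation(angle_deg: float, grating: MoireGratingPair) -> float:
    """Exact inverse of :func:`rotation_from_phase` (degrees -> radians)."""
    angle_deg = np.asarray(angle_deg, dtype=float)
    s = np.radians(angle_deg) / grating.n_refractive
    if np.any(np.abs(s) >= 1.0):
        raise ValueError(
            f"|angle| = {np.max(np.abs(angle_deg)):.3f} deg outside the invertible "
            f"domain (|theta_rad / n| < 1) of the moiré model")
    phase = 2.0 * np.pi * grating.f_front * grating.d * np.tan(np.arcsin(s))
    return phase if phase.ndim else float(phase)


def phase_wrap_rotation(grating: MoireGratingPair) -> float:
    """Rotation (degrees) at which the pair's moiré phase wraps through 2*pi."""
    return rotation_from_phase(2.0 * np.pi, grating)


# ---------------------------------------------------------------------------
# ArUco anchor dictionary
# ---------------------------------------------------------------------------

def _rotations(bits: np.ndarray):
    for k in range(4):
        yield np.rot90(bits, k)


def aruco_dictionary(n_codes: int = 4, seed: int = 7) -> list[np.ndarray]:
    """Deterministic family of 4x4 binary anchor codes.

    Codes are drawn from a seeded search and kept only if every rotation of
    every code is distinct from every rotation of every other code and from
    the other rotations of itself (so a detection fixes both the identity and
    the orientation of the square), and if the bit pattern is balanced enough
    to avoid confusing the decoder's black/white threshold.
    """
    rng = np.random.default_rng(seed)
    codes: list[np.ndarray] = []
    seen: set[bytes] = set()
    while len(codes) < n_codes:
        bits = rng.integers(0, 2, size=(4, 4)).astype(np.uint8)
        if not 5 <= bits.sum() <= 11:
            continue
        variants = [np.ascontiguousarray(r).tobytes() for r in _rotations(bits)]
        if len(set(variants)) < 4:  # rotationally self-similar
            continue
        if any(v in seen for v in variants):
            continue
        seen.update(variants)
        codes.append(bits)
    return codes


@dataclass
class ArucoAnchor:
    """One ArUco anchor square: identity plus its four outer corners.

    ``corners`` are in mm, marker frame, ordered canonically: top-left of the
    upright code pattern first, then clockwise as seen from the cameras
    (+Y up, +X right).
    """

    id: int
    corners: np.ndarray  # (4, 2) mm

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)


def _square_corners(cx: float, cy: float, size: float) -> np.ndarray:
    h = size / 2.0
    # top-left, top-right, bottom-right, bottom-left  (marker frame, +Y up)
    return np.array([
        [cx - h, cy + h],
        [cx + h, cy + h],
        [cx + h, cy - h],
        [cx - h, cy - h],
    ])


@dataclass
class MarkerSpec:
    """Complete geometry of the marker face.

    checkerboard: ``(rows, cols, square_mm)`` -- counts are squares; the
    checkerboard is centred on the marker origin.
    """

    checkerboard: tuple[int, int, float] = (6, 8, 3.0)
    aruco_anchors: list[ArucoAnchor] = field(default_factory=list)
    gratings: list[MoireGratingPair] = field(default_factory=list)
    face_size: tuple[float, float] = (64.0, 48.0)
    aruco_size: float = 8.0
    aruco_seed: int = 7

    def __post_init__(self) -> None:
        ids = [a.id for a in self.aruco_anchors]
        if len(self.aruco_anchors) != 4 or len(set(ids)) != 4:
            raise ValueError("marker requires exactly 4 ArUco anchors with distinct ids")
        if len(self.gratings) != 4:
            raise ValueError("marker requires 4 grating pairs (fine+coarse for pitch and yaw)")
        for axis in ("pitch", "yaw"):
            grades = sorted(g.grade for g in self.gratings if g.axis == axis)
            if grades != ["coarse", "fine"]:
                raise ValueError(f"need one fine and one coarse pair for {axis}")
        w, h = self.face_size
        cb = self._checkerboard_rect()
        for g in self.gratings:
            x0, y0, x1, y1 = g.region
            if not (-w / 2 <= x0 < x1 <= w / 2 and -h / 2 <= y0 < y1 <= h / 2):
                raise ValueError(f"grating region {g.region} outside the marker face")
            if not (x1 <= cb[0] or x0 >= cb[2] or y1 <= cb[1] or y0 >= cb[3]):
                raise ValueError(f"grating region {g.region} overlaps the checkerboard")
        for a in self.aruco_anchors:
            if np.any(np.abs(a.corners[:, 0]) > w / 2) or np.any(np.abs(a.corners[:, 1]) > h / 2):
                raise ValueError(f"anchor {a.id} extends outside the marker face")

    # -- geometry helpers ---------------------------------------------
    def _checkerboard_rect(self) -> tuple[float, float, float, float]:
        rows, cols, sq = self.checkerboard
        return (-cols * sq / 2, -rows * sq / 2, cols * sq / 2, rows * sq / 2)

    def checkerboard_inner_corners(self) -> np.ndarray:
        """Inner checkerboard corners in mm, marker frame, row-major from top-left."""
        rows, cols, sq = self.checkerboard
        xs = (np.arange(1, cols) - cols / 2) * sq
        ys = (rows / 2 - np.arange(1, rows)) * sq
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def anchor_by_id(self, anchor_id: int) -> ArucoAnchor:
        for a in self.aruco_anchors:
            if a.id == anchor_id:
                return a
        raise KeyError(f"no anchor with id {anchor_id}")

    def anchor_codes(self) -> dict[int, np.ndarray]:
        """Map anchor id -> 4x4 bit pattern."""
        codes = aruco_dictionary(len(self.aruco_anchors), seed=self.aruco_seed)
        return {a.id: codes[i] for i, a in enumerate(sorted(self.aruco_anchors, key=lambda a: a.id))}

    def grating(self, axis: str, grade: str) -> MoireGratingPair:
        for g in self.gratings:
            if g.axis == axis and g.grade == grade:
                return g
        raise KeyError(f"no {grade} {axis} grating")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "moiretrack-marker-v1",
            "checkerboard": list(self.checkerboard),
            "face_size": list(self.face_size),
            "aruco_size": self.aruco_size,
            "aruco_seed": self.aruco_seed,
            "aruco_anchors": [
                {"id": a.id, "corners": a.corners.tolist()} for a in self.aruco_anchors
            ],
            "gratings": [asdict(g) | {"region": list(g.region)} for g in self.gratings],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerSpec":
        if d.get("schema", "moiretrack-marker-v1") != "moiretrack-marker-v1":
            raise ValueError(f"unsupported marker schema {d.get('schema')!r}")
        return cls(
            checkerboard=tuple(d["checkerboard"]),
            face_size=tuple(d["face_size"]),
            aruco_size=d.get("aruco_size", 8.0),
            aruco_seed=d.get("aruco_seed", 7),
            aruco_anchors=[ArucoAnchor(a["id"], np.array(a["corners"])) for a in d["aruco_anchors"]],
            gratings=[
                MoireGratingPair(
                    f_front=g["f_front"], f_back=g["f_back"], d=g["d"],
                    n_refractive=g["n_refractive"], axis=g["axis"], grade=g["grade"],
                    region=tuple(g["region"]),
                )
                for g in d["gratings"]
            ],
        )

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path) -> "MarkerSpec":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


def default_marker_spec(n_refractive: float = DEFAULT_REFRACTIVE_INDEX,
                        d: float = 10.0) -> MarkerSpec:
    """Default marker layout: 64 x 48 mm face filling ~80% of the external
    cameras' 76 x 58 mm field of view at 3 m.

    Central 6x8 checkerboard of 3 mm squares, 8 mm ArUco anchors in the four
    corners, yaw grating pairs above/below the checkerboard (frequency along
    X) and pitch grating pairs left/right (frequency along Y).  Fine pairs are
    3.0/2.8 lines/mm, coarse pairs 1.7/1.6 lines/mm, on a 10 mm substrate.
    """
    anchors = [
        ArucoAnchor(0, _square_corners(-27.0, 19.0, 8.0)),
        ArucoAnchor(1, _square_corners(27.0, 19.0, 8.0)),
        ArucoAnchor(2, _square_corners(27.0, -19.0, 8.0)),
        ArucoAnchor(3, _square_corners(-27.0, -19.0, 8.0)),
    ]
    common = dict(d=d, n_refractive=n_refractive)
    gratings = [
        MoireGratingPair(3.0, 2.8, axis="yaw", grade="fine", region=(-18.0, 11.0, 18.0, 17.0), **common),
        MoireGratingPair(1.7, 1.6, axis="yaw", grade="coarse", region=(-18.0, -17.0, 18.0, -11.0), **common),
        MoireGratingPair(3.0, 2.8, axis="pitch", grade="fine", region=(-20.0, -13.0, -14.0, 13.0), **common),
        MoireGratingPair(1.7, 1.6, axis="pitch", grade="coarse", region=(14.0, -13.0, 20.0, 13.0), **common),
    ]
    return MarkerSpec(aruco_anchors=anchors, gratings=gratings)
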