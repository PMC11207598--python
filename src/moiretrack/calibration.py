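"""Camera calibration workflow.

The intrinsic/extrinsic parameters are estimated from multiple views of a
planar black-and-white calibration board (10 x 15 squares of 3 mm) using the
standard planar-homography (Zhang) method: a closed-form solution from the
per-view homographies, followed by joint Levenberg-Marquardt refinement of
the intrinsics, distortion and per-view board poses on the pixel
reprojection error.

The 50-image capture protocol mirrors the in-bore procedure: the field of
view is partitioned into a 3 x 3 grid; the board pauses at each cell for
five images (forward plus four single-axis tilts), then four extra
compound-tilt images and one final forward image are taken at the centre,
totalling 50.  The protocol is reproduced here as a deterministic placement
generator feeding a synthetic observation sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.sparse import lil_matrix
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .pose import CameraIntrinsics, solve_planar_pnp, _homography

__all__ = [
    "CalibrationBoardSpec",
    "BoardPlacement",
    "generate_calibration_protocol",
    "placement_pose",
    "simulate_observations",
    "estimate_intrinsics",
    "estimate_stereo_extrinsics",
]

TILTS = ("none", "left", "right", "up", "down")
COMPOUND_TILTS = ("top-left", "top-right", "bottom-left", "bottom-right")


@dataclass
class CalibrationBoardSpec:
    """Calibration checkerboard; counts are squares (inner corners are counts - 1)."""

    rows: int = 10
    cols: int = 15
    square: float = 3.0

    def __post_init__(self) -> None:
        if self.square <= 0:
            raise ValueError("square size must be positive")
        if self.rows < 3 or self.cols < 3:
            raise ValueError("board too small")

    @property
    def inner_corners(self) -> tuple[int, int]:
        return (self.rows - 1, self.cols - 1)

    def object_points(self) -> np.ndarray:
        """Inner-corner coordinates in the board plane (mm), centred, z implicit 0."""
        nr, nc = self.inner_corners
        xs = (np.arange(nc) - (nc - 1) / 2) * self.square
        ys = (np.arange(nr) - (nr - 1) / 2) * self.square
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class BoardPlacement:
    """One protocol stop: a FOV grid cell plus a board tilt."""

    grid_cell: tuple[int, int]  # (row, col) in the 3x3 FOV grid
    tilt: str

    def __post_init__(self) -> None:
        r, c = self.grid_cell
        if not (0 <= r <= 2 and 0 <= c <= 2):
            raise ValueError("grid cell must lie in the 3x3 FOV partition")
        if self.tilt not in TILTS + COMPOUND_TILTS:
            raise ValueError(f"unknown tilt {self.tilt!r}")
        if self.tilt in COMPOUND_TILTS and self.grid_cell != (1, 1):
            raise ValueError("compound tilts are taken only at the centre cell")


def generate_calibration_protocol() -> list[BoardPlacement]:
    """The deterministic 50-placement capture order.

    Nine grid cells (row-major) with five tilts each, then the four
    compound tilts and one final forward placement at the centre.
    """
    placements = [BoardPlacement((r, c), tilt)
                  for r in range(3) for c in range(3) for tilt in TILTS]
    placements += [BoardPlacement((1, 1), tilt) for tilt in COMPOUND_TILTS]
    placements.append(BoardPlacement((1, 1), "none"))
    return placements


_TILT_AXES = {
    "none": (0.0, 0.0),
    "left": (0.0, -1.0), "right": (0.0, 1.0),
    "up": (-1.0, 0.0), "down": (1.0, 0.0),
    "top-left": (-0.7, -0.7), "top-right": (-0.7, 0.7),
    "bottom-left": (0.7, -0.7), "bottom-right": (0.7, 0.7),
}


def placement_pose(placement: BoardPlacement, distance_mm: float = 3000.0,
                   spread_mm: tuple[float, float] = (22.0, 17.0),
                   tilt_deg: float = 18.0) -> RigidTransform:
    """Board-to-world pose for a protocol placement.

    The 3x3 grid cells are offset by ``spread_mm`` in X/Y around the camera
    axis (modelled on the slotted wooden stage: ~3 cm horizontal slot and
    0.7 cm vertical notches scaled to the FOV at 3 m); tilts rotate the board
    by ``tilt_deg`` about the in-plane axes.
    """
    r, c = placement.grid_cell
    offset = np.array([(c - 1) * spread_mm[0], (1 - r) * spread_mm[1], 0.0])
    ax, ay = _TILT_AXES[placement.tilt]
    R = Rotation.from_euler("xy", [ax * tilt_deg, ay * tilt_deg], degrees=True).as_matrix()
    return RigidTransform(rotation=R, translation=offset)


def simulate_stereo_observations(cam_left, cam_right, board: CalibrationBoardSpec,
                                 placements=None, noise_px: float = 0.0,
                                 seed: int = 0, distance_mm: float = 3000.0,
                                 jitter_mm: float = 2.0, jitter_deg: float = 2.0):
    """Paired synchronous views: one jittered board pose per placement,
    projected into both cameras (independent pixel noise per camera)."""
    from .geometry import euler_to_matrix

    placements = placements or generate_calibration_protocol()
    rng = np.random.default_rng(seed)
    obj = board.object_points()
    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    out_l, out_r = [], []
    for pl in placements:
        T = placement_pose(pl, distance_mm=distance_mm)
        if jitter_mm or jitter_deg:
            jr = euler_to_matrix(*rng.normal(0, jitter_deg, 3))
            jt = rng.normal(0, jitter_mm, 3)
            T = RigidTransform(rotation=T.rotation @ jr, translation=T.translation + jt)
        world = T.apply(obj3)
        for cam, store in ((cam_left, out_l), (cam_right, out_r)):
            px = cam.intrinsics.project(cam.world_to_cam.apply(world))
            if noise_px:
                px = px + rng.normal(0.0, noise_px, px.shape)
            store.append(px)
    return out_l, out_r


def simulate_observations(camera, board: CalibrationBoardSpec,
                          placements=None, noise_px: float = 0.0,
                          seed: int = 0, distance_mm: float = 3000.0,
                          jitter_mm: float = 2.0, jitter_deg: float = 2.0):
    """Project the board through a placed camera for each protocol placement.

    Returns a list of (N, 2) pixel corner arrays (the contract input of
    :func:`estimate_intrinsics`).  Small seeded pose jitter emulates manual
    repositioning of the stage.
    """
    from .geometry import euler_to_matrix

    placements = placements or generate_calibration_protocol()
    rng = np.random.default_rng(seed)
    obj = board.object_points()
    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    out = []
    for pl in placements:
        T = placement_pose(pl, distance_mm=distance_mm)
        if jitter_mm or jitter_deg:
            jr = euler_to_matrix(*rng.normal(0, jitter_deg, 3))
            jt = rng.normal(0, jitter_mm, 3)
            T = RigidTransform(rotation=T.rotation @ jr, translation=T.translation + jt)
        world = T.apply(obj3)
        cam = camera.world_to_cam.apply(world)
        px = camera.intrinsics.project(cam)
        if noise_px:
            px = px + rng.normal(0.0, noise_px, px.shape)
        out.append(px)
    return out


# ---------------------------------------------------------------------------
# Zhang closed form + refinement
# ---------------------------------------------------------------------------

def _vij(H, i, j):
    return np.array([
        H[0, i] * H[0, j],
        H[0, i] * H[1, j] + H[1, i] * H[0, j],
        H[1, i] * H[1, j],
        H[2, i] * H[0, j] + H[0, i] * H[2, j],
        H[2, i] * H[1, j] + H[1, i] * H[2, j],
        H[2, i] * H[2, j],
    ])


def _intrinsics_closed_form(Hs, resolution):
    V = []
    for H in Hs:
        V.append(_vij(H, 0, 1))
        V.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    V = np.asarray(V)
    _, s, vt = np.linalg.svd(V)
    b = vt[-1]
    B11, B12, B22, B13, B23, B33 = b
    denom = B11 * B22 - B12 ** 2
    try:
        with np.errstate(divide="raise", invalid="raise"):
            cy = (B12 * B13 - B11 * B23) / denom
            lam = B33 - (B13 ** 2 + cy * (B12 * B13 - B11 * B23)) / B11
            fx = np.sqrt(lam / B11)
            fy = np.sqrt(lam * B11 / denom)
            cx = -B13 * fx ** 2 / lam
        ok = np.isfinite([fx, fy, cx, cy]).all() and fx > 0 and fy > 0
    except (ZeroDivisionError, FloatingPointError, ValueError):
        ok = False
    if not ok:
        raise ValueError("degenerate calibration geometry (closed form failed)")
    return float(fx), float(fy), float(cx), float(cy)


def _extrinsic_from_homography(K, H):
    A = np.linalg.inv(K) @ H
    lam = 2.0 / (np.linalg.norm(A[:, 0]) + np.linalg.norm(A[:, 1]))
    if A[2, 2] * lam < 0:
        lam = -lam
    r1, r2, t = lam * A[:, 0], lam * A[:, 1], lam * A[:, 2]
    Rm = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(Rm)
    return u @ np.diag([1, 1, np.linalg.det(u @ vt)]) @ vt, t


def estimate_intrinsics(observations, board: CalibrationBoardSpec,
                        resolution=(720, 480), n_dist_coeffs: int = 2,
                        min_views: int = 3):
    """Planar (Zhang) intrinsic calibration from per-image corner sets.

    Parameters
    ----------
    observations:
        list of (N, 2) detected/pixel corner arrays, one per image, ordered
        like ``board.object_points()``.
    n_dist_coeffs:
        number of radial coefficients (k1, k2) refined; tangential terms are
        held at zero for the synthetic, distortionless presets.

    Returns
    -------
    (CameraIntrinsics, report) where report contains per-image and mean
    reprojection RMS in pixels.
    """
    obj = board.object_points()
    observations = [np.asarray(o, dtype=float) for o in observations]
    if len(observations) < min_views:
        raise ValueError(f"need at least {min_views} views, got {len(observations)}")
    for o in observations:
        if o.shape != (len(obj), 2):
            raise ValueError("observation shape does not match the board corner count")
    Hs = [_homography(obj, o) for o in observations]

    # fronto-parallel-only geometry leaves the closed form rank-deficient
    try:
        fx, fy, cx, cy = _intrinsics_closed_form(Hs, resolution)
    except ValueError:
        raise ValueError("under-determined calibration: views are degenerate "
                         "(e.g. all fronto-parallel); add tilted views")

    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    poses = []
    for H in Hs:
        R, t = _extrinsic_from_homography(K, H)
        poses.append(np.concatenate([Rotation.from_matrix(R).as_rotvec(), t]))

    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    n_views = len(observations)
    n_intr = 4 + n_dist_coeffs

    def unpack(p):
        intr = CameraIntrinsics(fx=p[0], fy=p[1], cx=p[2], cy=p[3],
                                distortion=np.concatenate([p[4:n_intr],
                                                           np.zeros(5 - n_dist_coeffs)]),
                                resolution=resolution)
        return intr, p[n_intr:].reshape(n_views, 6)

    def residual(p):
        intr, vp = unpack(p)
        out = []
        for (pv, px) in zip(vp, observations):
            R = Rotation.from_rotvec(pv[:3]).as_matrix()
            cam = obj3 @ R.T + pv[3:]
            out.append((intr.project(cam) - px).ravel())
        return np.concatenate(out)

    p0 = np.concatenate([[fx, fy, cx, cy], np.zeros(n_dist_coeffs),
                         np.concatenate(poses)])
    m = 2 * len(obj) * n_views
    spars = lil_matrix((m, p0.size), dtype=int)
    spars[:, :n_intr] = 1
    rows_per = 2 * len(obj)
    for v in range(n_views):
        spars[v * rows_per:(v + 1) * rows_per, n_intr + 6 * v:n_intr + 6 * (v + 1)] = 1
    res = optimize.least_squares(residual, p0, jac_sparsity=spars, method="trf",
                                 x_scale="jac", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                 max_nfev=100)
    intr, vp = unpack(res.x)
    per_image = []
    for (pv, px) in zip(vp, observations):
        R = Rotation.from_rotvec(pv[:3]).as_matrix()
        err = intr.project(obj3 @ R.T + pv[3:]) - px
        per_image.append(float(np.sqrt(np.mean(err ** 2))))
    report = {
        "per_image_rms_px": per_image,
        "mean_rms_px": float(np.sqrt(np.mean(res.fun ** 2))),
        "n_views": n_views,
    }
    return intr, report


def estimate_stereo_extrinsics(obs_left, obs_right, left: CameraIntrinsics,
                               right: CameraIntrinsics, board: CalibrationBoardSpec
                               ) -> tuple[RigidTransform, float]:
    """Right-to-left rigid transform from paired synchronous board views.

    Initialised by averaging the per-view relative transforms (quaternion
    mean for rotation), then refined by a joint bundle adjustment over the
    extrinsic and the per-view board poses on both cameras' reprojection
    error -- essential at the ~1.5 degree field of view, where individual
    planar PnP poses have large depth/tilt uncertainty.  Returns
    (extrinsic right->left, total reprojection RMS in px).
    """
    if len(obs_left) != len(obs_right):
        raise ValueError("unpaired observation counts")
    if not obs_left:
        raise ValueError("no observations")
    obj = board.object_points()
    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    rels = []
    lposes = []
    for ol, orr in zip(obs_left, obs_right):
        pl = solve_planar_pnp(obj, ol, left)
        pr = solve_planar_pnp(obj, orr, right)
        rels.append(pl.transform @ pr.transform.inverse())
        lposes.append(pl.transform)
    Rmean = Rotation.from_matrix(np.stack([r.rotation for r in rels])).mean().as_matrix()
    tmean = np.mean([r.translation for r in rels], axis=0)

    n_views = len(obs_left)
    ext = np.concatenate([Rotation.from_matrix(Rmean).as_rotvec(), tmean])
    views = [np.concatenate([Rotation.from_matrix(T.rotation).as_rotvec(), T.translation])
             for T in lposes]

    def view_residual(pv, ext_p, ol, orr):
        Rv = Rotation.from_rotvec(pv[:3]).as_matrix()
        cam_l = obj3 @ Rv.T + pv[3:]
        R_rl = Rotation.from_rotvec(ext_p[:3]).as_matrix()
        cam_r = (cam_l - ext_p[3:]) @ R_rl
        return np.concatenate([(left.project(cam_l) - ol).ravel(),
                               (right.project(cam_r) - orr).ravel()])

    def ext_residual(ext_p):
        R_rl = Rotation.from_rotvec(ext_p[:3]).as_matrix()
        out = []
        for pv, orr in zip(views, obs_right):
            Rv = Rotation.from_rotvec(pv[:3]).as_matrix()
            cam_r = (obj3 @ Rv.T + pv[3:] - ext_p[3:]) @ R_rl
            out.append((right.project(cam_r) - orr).ravel())
        return np.concatenate(out)

    # alternate: stereo-refit each view pose (well-conditioned: two views pin
    # down depth and tilt), then refit the 6 extrinsic parameters
    prev = np.inf
    for _ in range(12):
        for v in range(n_views):
            views[v] = optimize.least_squares(
                view_residual, views[v], args=(ext, obs_left[v], obs_right[v]),
                method="lm", xtol=1e-12, ftol=1e-12).x
        res = optimize.least_squares(ext_residual, ext, method="lm",
                                     xtol=1e-12, ftol=1e-12)
        ext = res.x
        cost = float(np.sqrt(np.mean(res.fun ** 2)))
        if prev - cost < 1e-8:
            break
        prev = cost

    T = RigidTransform(rotation=Rotation.from_rotvec(ext[:3]).as_matrix(),
                       translation=ext[3:6])
    # total reprojection RMS over both cameras with the final poses
    total = np.concatenate([view_residual(pv, ext, ol, orr)
                            for pv, ol, orr in zip(views, obs_left, obs_right)])
    rms = float(np.sqrt(np.mean(total ** 2)))
    return T, rms
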