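"""Synthetic scene rendering: marker views and a procedural head proxy.

This module replaces the physical benchtop/in-bore rig (and the external
Blender + scanned-head assets used for the markerless-system simulations)
with fully procedural renderers, so that every stage of the pipeline can be
validated against commanded ground-truth poses without hardware or
downloads.

Marker rendering
----------------
Every output pixel casts a ray (2x2 supersampled, then box-downsampled to
suppress aliasing of the ~3 lines/mm gratings) through the camera model into
the marker frame and intersects the marker plane.  Checkerboard, ArUco
anchors and the near grating print are evaluated at the front-surface
intersection; the far grating print is sampled where the ray, refracted into
the substrate by Snell's law, crosses the far surface at depth ``d``.  The
moiré beat pattern and its rotation/phase behaviour are therefore emergent
physics, not a painted-on sinusoid: the higher-frequency print of each pair
is laid on the far surface, which makes the beat-phase shift for a rotation
``theta`` exactly ``2*pi*f1*d*tan(asin(sin(theta)/n))`` -- the inverse of
the rotation/phase model in :mod:`moiretrack.marker` up to the
``sin(theta) ~ theta`` difference (< 5e-4 deg at 2 deg).

Camera presets
--------------
* ``external``: the wall-mounted tracking cameras -- 720x480 px covering a
  76 x 58 mm field of view at 3 m (200 mm-equivalent lens).
* ``inbore``: the in-bore head cameras -- 720x480 px covering 151 x 112 mm
  (6 mm lens, ~4.5 px/mm at the head).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Pose6DOF, RigidTransform, look_at
from .marker import MarkerSpec
from .detection import Frame
from .pose import CameraIntrinsics, StereoRig

__all__ = [
    "RenderOptions",
    "PlacedCamera",
    "HeadProxyParams",
    "MarkerOutOfViewError",
    "external_camera",
    "external_stereo",
    "inbore_camera",
    "render_marker_view",
    "render_stereo",
    "render_head_proxy",
]


class MarkerOutOfViewError(RuntimeError):
    """Raised when the target does not project inside the camera frame."""


@dataclass
class RenderOptions:
    """Image-degradation model applied after the geometric render.

    glare patches are ``(cx_px, cy_px, rx_px, ry_px, intensity)`` ellipses;
    occlusion masks are ``(x0, y0, x1, y1, grey)`` pixel rectangles painted
    over the scene (e.g. a cable crossing the view).
    """

    noise_sigma: float = 0.0          # grey levels
    blur_sigma: float = 0.6           # optical PSF, px (applied before downsampling)
    illumination_gradient: float = 0.0  # fractional left-right ramp
    glare: list[tuple] = field(default_factory=list)
    occlusions: list[tuple] = field(default_factory=list)
    background: float = 60.0
    seed: int | None = None
    supersample: int = 2

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise and blur sigmas must be >= 0")
        if self.supersample < 1:
            raise ValueError("supersample factor must be >= 1")


@dataclass
class PlacedCamera:
    """A camera model plus its placement in the world frame."""

    intrinsics: CameraIntrinsics
    world_to_cam: RigidTransform
    camera_id: str = "cam"

    @property
    def center(self) -> np.ndarray:
        return self.world_to_cam.inverse().translation


# ---------------------------------------------------------------------------
# Camera presets
# ---------------------------------------------------------------------------

EXTERNAL_DISTANCE_MM = 3000.0
EXTERNAL_FOV_MM = (76.0, 58.0)
INBORE_FOV_MM = (151.0, 112.0)
INBORE_DISTANCE_MM = 240.0


def _fov_intrinsics(fov_mm, distance, resolution) -> CameraIntrinsics:
    w, h = resolution
    return CameraIntrinsics(fx=w * distance / fov_mm[0], fy=h * distance / fov_mm[1],
                            cx=w / 2.0, cy=h / 2.0, resolution=resolution)


def external_camera(resolution=(720, 480), offset=(0.0, 0.0)) -> PlacedCamera:
    """Single wall-mounted tracking camera, centred on the marker at 3 m."""
    intr = _fov_intrinsics(EXTERNAL_FOV_MM, EXTERNAL_DISTANCE_MM, resolution)
    center = np.array([offset[0], offset[1], EXTERNAL_DISTANCE_MM])
    return PlacedCamera(intr, look_at(center, (0, 0, 0)), camera_id="external")


def external_stereo(baseline_mm: float = 600.0, resolution=(720, 480)
                    ) -> tuple[StereoRig, PlacedCamera, PlacedCamera]:
    """Stereo pair of external cameras, toed in to view the marker at 3 m."""
    intr = _fov_intrinsics(EXTERNAL_FOV_MM, EXTERNAL_DISTANCE_MM, resolution)
    left = PlacedCamera(intr, look_at((-baseline_mm / 2, 0, EXTERNAL_DISTANCE_MM),
                                      (0, 0, 0)), camera_id="left")
    right = PlacedCamera(intr, look_at((baseline_mm / 2, 0, EXTERNAL_DISTANCE_MM),
                                       (0, 0, 0)), camera_id="right")
    extrinsic = left.world_to_cam @ right.world_to_cam.inverse()  # right -> left
    return StereoRig(left=intr, right=intr, extrinsic=extrinsic), left, right


def inbore_camera(side: str = "left", resolution=(720, 480)) -> PlacedCamera:
    """In-bore head camera, viewing the face obliquely from above."""
    intr = _fov_intrinsics(INBORE_FOV_MM, INBORE_DISTANCE_MM, resolution)
    az = np.radians(-25.0 if side == "left" else 25.0)
    el = np.radians(15.0)
    r = INBORE_DISTANCE_MM
    center = np.array([r * np.sin(az) * np.cos(el), r * np.sin(el),
                       r * np.cos(az) * np.cos(el)])
    return PlacedCamera(intr, look_at(center, (0, 0, 0)), camera_id=f"inbore:{side}")


# ---------------------------------------------------------------------------
# Ray machinery
# ---------------------------------------------------------------------------

_RAY_CACHE: dict[tuple, np.ndarray] = {}


def _ray_dirs(intr: CameraIntrinsics, ss: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Normalised camera-frame ray directions (3, H*ss*W*ss) plus the grid shape."""
    key = (intr.fx, intr.fy, intr.cx, intr.cy, intr.resolution, ss)
    if key not in _RAY_CACHE:
        w, h = intr.resolution
        # pixel j is centred on continuous coordinate j (array-index convention);
        # the ss subsamples straddle it symmetrically
        xs = (np.arange(w * ss) + 0.5) / ss - 0.5
        ys = (np.arange(h * ss) + 0.5) / ss - 0.5
        dx = ((xs - intr.cx) / intr.fx).astype(np.float32)
        dy = ((ys - intr.cy) / intr.fy).astype(np.float32)
        gx, gy = np.meshgrid(dx, dy)
        d = np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size, dtype=np.float32)])
        d /= np.sqrt(np.sum(d * d, axis=0, keepdims=True))
        _RAY_CACHE[key] = (np.ascontiguousarray(d), (h * ss, w * ss))
    return _RAY_CACHE[key]


def _downsample(img: np.ndarray, ss: int, blur_sigma: float = 0.0) -> np.ndarray:
    """Optical PSF blur (sigma in output px) applied on the supersampled grid,
    then box-downsample; blurring before the decimation is what suppresses
    aliasing of the fine grating harmonics."""
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma * ss, truncate=3.0)
    if ss == 1:
        return img
    h, w = img.shape
    return img.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def _finalize(img: np.ndarray, opts: RenderOptions, rng: np.random.Generator | None,
              timestamp: float, camera_id: str) -> Frame:
    h, w = img.shape
    if opts.illumination_gradient:
        ramp = 1.0 + opts.illumination_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        img = img * ramp[None, :]
    for (cx, cy, rx, ry, inten) in opts.glare:
        yy, xx = np.mgrid[0:h, 0:w]
        img = img + inten * np.exp(-(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2))
    for (x0, y0, x1, y1, grey) in opts.occlusions:
        img[int(y0):int(y1), int(x0):int(x1)] = grey
    if opts.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(opts.seed)
        img = img + rng.normal(0.0, opts.noise_sigma, img.shape)
    img = np.clip(img, 0, 255)
    return Frame(pixels=np.round(img).astype(np.uint8), timestamp=timestamp,
                 camera_id=camera_id)


# ---------------------------------------------------------------------------
# Marker texture
# ---------------------------------------------------------------------------

_WHITE = 235.0
_BLACK = 28.0
_INK_TRANSMITTANCE = 0.12  # residual transmittance of a printed line


def _square_wave(coord: np.ndarray, freq: float) -> np.ndarray:
    """Transmittance of a line print: 50% duty cycle at ``freq`` lines/mm."""
    on = np.mod(coord * freq, 1.0) < 0.5
    return np.where(on, 1.0, _INK_TRANSMITTANCE)


def _marker_texture(u: np.ndarray, v: np.ndarray, dirs_m: np.ndarray,
                    spec: MarkerSpec, background: float) -> np.ndarray:
    """Marker-face grey level at marker-frame coordinates (u, v) for viewing
    directions ``dirs_m`` (3, N unit vectors pointing away from the camera)."""
    w, h = spec.face_size
    out = np.full(u.shape, background)
    face = (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)
    out[face] = _WHITE

    # checkerboard
    rows, cols, sq = spec.checkerboard
    cb_x0, cb_y0, cb_x1, cb_y1 = -cols * sq / 2, -rows * sq / 2, cols * sq / 2, rows * sq / 2
    in_cb = face & (u >= cb_x0) & (u < cb_x1) & (v >= cb_y0) & (v < cb_y1)
    if in_cb.any():
        ci = np.floor((u[in_cb] - cb_x0) / sq)
        ri = np.floor((cb_y1 - v[in_cb]) / sq)
        dark = np.mod(ci + ri, 2) == 0
        out[in_cb] = np.where(dark, _BLACK, _WHITE)

    # ArUco anchors: 6x6 cell grid (1-cell black border + 4x4 code)
    codes = spec.anchor_codes()
    for anchor in spec.aruco_anchors:
        c = anchor.corners
        x0, x1 = c[:, 0].min(), c[:, 0].max()
        y0, y1 = c[:, 1].min(), c[:, 1].max()
        inside = face & (u >= x0) & (u < x1) & (v >= y0) & (v < y1)
        if not inside.any():
            continue
        cell = (x1 - x0) / 6.0
        col = np.clip(((u[inside] - x0) / cell).astype(int), 0, 5)
        row = np.clip(((y1 - v[inside]) / cell).astype(int), 0, 5)
        grid = np.zeros((6, 6), dtype=np.uint8)  # 0 = black border
        grid[1:5, 1:5] = codes[anchor.id]
        out[inside] = np.where(grid[row, col], _WHITE, _BLACK)

    # moiré grating pairs: near print sampled at the surface point, far print
    # sampled where the refracted ray crosses the far surface
    for g in spec.gratings:
        x0, y0, x1, y1 = g.region
        inside = face & (u >= x0) & (u < x1) & (v >= y0) & (v < y1)
        if not inside.any():
            continue
        k = dirs_m[:, inside]
        # vector Snell refraction at the z=0 surface (normal +Z, ray going -Z)
        n = g.n_refractive
        tx, ty = k[0] / n, k[1] / n
        tz = -np.sqrt(np.maximum(1.0 - tx ** 2 - ty ** 2, 1e-12))
        scale = g.d / np.abs(tz)
        du = tx * scale
        dv = ty * scale
        if g.profile_axis == "x":
            c_near = u[inside] - x0
            c_far = c_near + du
        else:
            c_near = v[inside] - y0
            c_far = c_near + dv
        t_near = _square_wave(c_near, g.f_back)
        t_far = _square_wave(c_far, g.f_front)
        out[inside] = _WHITE * t_near * t_far
    return out


def _marker_in_fov(pose: Pose6DOF, camera: PlacedCamera, spec: MarkerSpec) -> bool:
    w, h = spec.face_size
    corners_m = np.array([[-w / 2, -h / 2, 0], [w / 2, -h / 2, 0],
                          [w / 2, h / 2, 0], [-w / 2, h / 2, 0]])
    world = pose.to_transform().apply(corners_m)
    cam = camera.world_to_cam.apply(world)
    if np.any(cam[:, 2] <= 0):
        return False
    px = camera.intrinsics.project(cam)
    rw, rh = camera.intrinsics.resolution
    return bool(np.all((px[:, 0] >= 0) & (px[:, 0] < rw) &
                       (px[:, 1] >= 0) & (px[:, 1] < rh)))


def render_marker_view(pose: Pose6DOF, camera: PlacedCamera, spec: MarkerSpec,
                       opts: RenderOptions | None = None,
                       rng: np.random.Generator | None = None,
                       timestamp: float = 0.0) -> Frame:
    """Render one grayscale view of the marker at the commanded pose."""
    opts = opts or RenderOptions()
    if not _marker_in_fov(pose, camera, spec):
        raise MarkerOutOfViewError("marker face does not project fully inside the frame")
    ss = opts.supersample
    d, shape = _ray_dirs(camera.intrinsics, ss)

    T_pose = pose.to_transform()
    R_cam_to_world = camera.world_to_cam.rotation.T
    R = (T_pose.rotation.T @ R_cam_to_world).astype(np.float32)  # camera dirs -> marker
    o = T_pose.inverse().apply(camera.center).astype(np.float32)  # camera centre, marker frame
    k = R @ d
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -o[2] / k[2]
    np.putmask(s, ~(np.isfinite(s) & (s > 0)), np.float32(np.inf))
    u = o[0] + s * k[0]
    v = o[1] + s * k[1]
    np.putmask(u, ~np.isfinite(u), np.float32(1e9))
    np.putmask(v, ~np.isfinite(v), np.float32(1e9))
    grey = _marker_texture(u, v, k, spec, opts.background)
    img = _downsample(grey.reshape(shape), ss, opts.blur_sigma)
    return _finalize(img, opts, rng, timestamp, camera.camera_id)


def render_stereo(pose: Pose6DOF, left: PlacedCamera, right: PlacedCamera,
                  spec: MarkerSpec, opts: RenderOptions | None = None,
                  rng: np.random.Generator | None = None,
                  timestamp: float = 0.0) -> tuple[Frame, Frame]:
    """Render a synchronous stereo frame pair of the marker."""
    fl = render_marker_view(pose, left, spec, opts, rng=rng, timestamp=timestamp)
    fr = render_marker_view(pose, right, spec, opts, rng=rng, timestamp=timestamp)
    return fl, fr


# ---------------------------------------------------------------------------
# Procedural head proxy
# ---------------------------------------------------------------------------

@dataclass
class HeadProxyParams:
    """Procedural stand-in for a scanned head model.

    An ellipsoid with Lambert shading, a seeded smooth albedo texture and a
    handful of shaded facial primitives (eyes, nose ridge, mouth line) that
    move rigidly with the head.  Deliberately not photorealistic; it provides
    a deterministic, pose-sensitive target at the in-bore camera scale.
    """

    axes: tuple[float, float, float] = (70.0, 90.0, 80.0)  # mm half-axes
    texture_seed: int = 0
    n_texture_waves: int = 16
    skin_level: float = 0.8   # base albedo, 0..1
    feature_strength: float = 0.6

    def __post_init__(self) -> None:
        if not all(30.0 <= a <= 150.0 for a in self.axes):
            raise ValueError("ellipsoid axes outside human-plausible bounds (30-150 mm)")
        if not (0.1 <= self.skin_level <= 1.0):
            raise ValueError("skin_level must be in [0.1, 1]")


def _texture_waves(params: HeadProxyParams):
    # wave numbers up to ~0.5 cycles/mm (2 mm wavelength, ~2.4 px at the
    # in-bore scale): fine enough that sub-mm motion moves measurable
    # intensity everywhere, coarse enough not to alias at 180x120 inputs
    rng = np.random.default_rng(params.texture_seed)
    kdir = rng.normal(size=(params.n_texture_waves, 3))
    kdir /= np.linalg.norm(kdir, axis=1, keepdims=True)
    kmag = rng.uniform(0.08, 0.5, params.n_texture_waves)
    phase = rng.uniform(0, 2 * np.pi, params.n_texture_waves)
    amp = rng.uniform(0.5, 1.0, params.n_texture_waves)
    amp /= amp.sum()
    return kdir * kmag[:, None], phase, amp


_FEATURES = [  # (x, y) on the +Z face, sigma_mm, strength sign
    ((-26.0, 18.0), 8.0, -1.0),   # left eye
    ((26.0, 18.0), 8.0, -1.0),    # right eye
    ((0.0, -2.0), 6.0, +0.7),     # nose tip highlight
    ((0.0, -32.0), (14.0, 4.0), -0.8),  # mouth line (anisotropic)
]


def render_head_proxy(pose: Pose6DOF, camera: PlacedCamera, params: HeadProxyParams,
                      opts: RenderOptions | None = None,
                      rng: np.random.Generator | None = None,
                      timestamp: float = 0.0) -> Frame:
    """Render the head proxy at the commanded pose (bounds ~ +-5 mm / deg)."""
    opts = opts or RenderOptions()
    ss = max(1, opts.supersample)
    d, shape = _ray_dirs(camera.intrinsics, ss)

    T_pose = pose.to_transform()
    R = T_pose.rotation.T @ camera.world_to_cam.rotation.T  # camera dirs -> head frame
    o = T_pose.inverse().apply(camera.center)
    k = R @ d
    ax = np.asarray(params.axes)
    op = o[:, None] / ax[:, None]
    kp = k / ax[:, None]
    a = np.sum(kp * kp, axis=0)
    b = np.sum(op * kp, axis=0)
    c = float(np.sum(op[:, 0] ** 2)) - 1.0
    disc = b * b - a * c
    hit = disc > 0
    t = np.full(k.shape[1], np.nan)
    t[hit] = (-b[hit] - np.sqrt(disc[hit])) / a[hit]
    hit &= t > 0
    p = o[:, None] + t * k  # surface points, head frame (NaN off-surface)
    grey = np.full(k.shape[1], opts.background)
    if hit.any():
        ph = p[:, hit]
        normal = ph / (ax[:, None] ** 2)
        normal = normal / np.linalg.norm(normal, axis=0)
        light = np.array([0.25, 0.45, 0.86])
        light = T_pose.rotation.T @ (light / np.linalg.norm(light))  # light fixed in world
        lam = 0.25 + 0.75 * np.clip(np.sum(normal * light[:, None], axis=0), 0, None)
        kvec, phw, amp = _texture_waves(params)
        tex = np.zeros(ph.shape[1])
        for kk, pp, aa in zip(kvec, phw, amp):
            tex += aa * np.cos(kk @ ph + pp)
        albedo = params.skin_level * (1.0 + 0.7 * tex)
        for (fx, fy), sig, strength in _FEATURES:
            if np.isscalar(sig):
                sx = sy = sig
            else:
                sx, sy = sig
            r2 = ((ph[0] - fx) / sx) ** 2 + ((ph[1] - fy) / sy) ** 2
            front = ph[2] > 0
            albedo = albedo * (1.0 + params.feature_strength * strength *
                               np.exp(-0.5 * r2) * front)
        grey[hit] = np.clip(235.0 * albedo * lam, 0, 255)
    img = _downsample(grey.reshape(shape), ss, opts.blur_sigma)
    return _finalize(img, opts, rng, timestamp, camera.camera_id)
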