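"""Frame-analysis pipeline for the moiré marker.

Per frame: detect the four ArUco anchor squares, rectify the marker face to
a rectilinear grid with a homography, average each moiré region into a 1-D
profile, fit the profile with a sinusoid to extract the beat phase, and
difference phases against a reference frame to obtain through-plane
rotations via the fine/coarse grating pairs.

A frame in which fewer than all four anchors decode is flagged occluded and
contributes no pose sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import measure
from skimage.transform import ProjectiveTransform

from .marker import MarkerSpec, MoireGratingPair, rotation_from_phase

__all__ = [
    "Frame",
    "ArUcoDetection",
    "MoireProfile",
    "PhaseMeasurement",
    "RectifiedMarker",
    "OcclusionError",
    "PhaseFitError",
    "detect_aruco",
    "rectify_marker",
    "extract_moire_profile",
    "fit_moire_phase",
    "through_plane_rotation",
    "analyse_frame",
]


class OcclusionError(RuntimeError):
    """Raised when the marker cannot be analysed because anchors are missing."""


def _estimate_projective(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform | None:
    """Homography estimate across skimage API generations; None when degenerate."""
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        return tf if tf else None
    tf = ProjectiveTransform()
    return tf if tf.estimate(src, dst) else None


class PhaseFitError(RuntimeError):
    """Raised when the sinusoid fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, residual_rms: float | None = None):
        super().__init__(message)
        self.residual_rms = residual_rms


@dataclass
class Frame:
    """One grayscale video frame (pixel values 0-255)."""

    pixels: np.ndarray
    timestamp: float = 0.0
    camera_id: str = "cam"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:  # colour input: ITU-R 601 luma
            px = px[..., 0] * 0.299 + px[..., 1] * 0.587 + px[..., 2] * 0.114
        self.pixels = np.asarray(px, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ArUcoDetection:
    """A decoded anchor square: id plus its 4 sub-pixel corners.

    ``corners`` are (4, 2) pixel coordinates (x, y) in canonical order: the
    top-left corner of the upright code pattern first, then clockwise around
    the pattern, matching the anchor-corner order in :class:`MarkerSpec`.
    """

    id: int
    corners: np.ndarray

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)


@dataclass
class MoireProfile:
    """Averaged 1-D moiré signal for one grating region."""

    values: np.ndarray          # grayscale means, length L
    positions: np.ndarray       # pixel coordinate s along the profile
    n_lines: int                # number of pixel lines averaged
    grating_ref: MoireGratingPair
    mm_per_px: float            # rectified-grid sampling pitch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.shape != self.positions.shape:
            raise ValueError("values and positions must have equal length")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    @property
    def expected_omega(self) -> float:
        """Nominal beat angular frequency in rad/pixel along the profile."""
        return 2.0 * np.pi * self.grating_ref.beat_frequency * self.mm_per_px


@dataclass
class PhaseMeasurement:
    """Parameters of the sinusoid A*sin(omega*s - phi) + b fitted to a profile."""

    amplitude: float
    omega: float
    phase: float
    offset: float
    residual_rms: float
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# ArUco detection
# ---------------------------------------------------------------------------

def _order_quad(pts: np.ndarray) -> np.ndarray:
    """Order 4 points counter-clockwise in image coordinates, starting anywhere."""
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    return pts[np.argsort(ang)]


def _quad_from_mask(mask: np.ndarray, bbox) -> np.ndarray | None:
    """Extract a coarse 4-corner polygon from a filled component mask.

    Corners are picked from the convex hull of the component boundary: the
    most distant vertex pair forms a diagonal and the two vertices farthest
    from it on either side complete the quadrilateral.
    """
    from scipy.spatial import ConvexHull, QhullError

    r0, c0, r1, c1 = bbox
    sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=float)
    sub[1:-1, 1:-1] = mask[r0:r1, c0:c1]
    contours = measure.find_contours(sub, 0.5)
    if not contours:
        return None
    # a border square yields outer and inner ring contours; the convex hull of
    # their union is the outer quadrilateral
    contour = np.vstack(contours)
    xy = np.column_stack([contour[:, 1] + c0 - 1, contour[:, 0] + r0 - 1])
    try:
        hull = xy[ConvexHull(xy).vertices]
    except QhullError:
        return None
    if len(hull) < 4:
        return None
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    a, b = hull[i], hull[j]
    ab = b - a
    cross = (hull[:, 0] - a[0]) * ab[1] - (hull[:, 1] - a[1]) * ab[0]
    if cross.max() <= 0 or cross.min() >= 0:
        return None  # all hull points on one side: degenerate
    k = int(np.argmax(cross))
    m = int(np.argmin(cross))
    return _order_quad(np.stack([a, b, hull[k], hull[m]]))


def _sample(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``img`` at (x, y) pixel positions."""
    return ndimage.map_coordinates(img, [xy[..., 1].ravel(), xy[..., 0].ravel()],
                                   order=1, mode="nearest").reshape(xy.shape[:-1])


def _refine_quad_edges(img: np.ndarray, quad: np.ndarray,
                       n_samples: int = 12, half_len: float = 2.5) -> np.ndarray:
    """Sub-pixel corner refinement by fitting straight lines to the four edges.

    For each edge, intensity profiles are sampled perpendicular to the edge at
    several stations; the edge crossing is located at the extremum of the
    finite-difference gradient with parabolic interpolation, a line is fitted
    to the crossings, and adjacent lines are intersected to give the corners.
    """
    lines = []
    offs = np.linspace(-half_len, half_len, 21)
    step = offs[1] - offs[0]
    for i in range(4):
        p0, p1 = quad[i], quad[(i + 1) % 4]
        edge = p1 - p0
        t = edge / np.linalg.norm(edge)
        nvec = np.array([-t[1], t[0]])
        # stations away from the corners, where the edge is clean
        s = np.linspace(0.2, 0.8, n_samples)
        stations = p0 + s[:, None] * edge
        grid = stations[:, None, :] + offs[None, :, None] * nvec
        prof = _sample(img, grid)
        # sub-pixel edge = 50% crossing between the two sides' intensity levels
        lo = prof.min(axis=1)
        hi = prof.max(axis=1)
        mid = 0.5 * (lo + hi)
        sgn = np.sign(prof - mid[:, None])
        crossing = np.diff(sgn, axis=1) != 0
        cost = np.where(crossing, np.abs(offs[:-1][None, :]), np.inf)
        ci = np.argmin(cost, axis=1)
        rows = np.arange(len(s))
        ok = (hi - lo > 30) & np.isfinite(cost[rows, ci])
        if ok.sum() < 4:
            return quad
        denom = prof[rows, ci + 1] - prof[rows, ci]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(np.abs(denom) > 1e-9, (mid - prof[rows, ci]) / denom, 0.5)
        d = offs[ci] + np.clip(frac, 0, 1) * step
        pts = stations[ok] + d[ok, None] * nvec
        # total least squares line fit through the edge points
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        direction = vt[0]
        normal = np.array([-direction[1], direction[0]])
        lines.append((normal, np.dot(normal, c)))
    corners = []
    for i in range(4):
        (n1, d1), (n2, d2) = lines[i - 1], lines[i]
        A = np.stack([n1, n2])
        if np.abs(np.linalg.det(A)) < 1e-9:
            return quad  # near-parallel edges; keep the coarse quad
        corners.append(np.linalg.solve(A, [d1, d2]))
    return np.asarray(corners)


def _decode_bits(img: np.ndarray, quad: np.ndarray, black: float, white: float
                 ) -> np.ndarray | None:
    """Sample the 6x6 cell grid of a candidate square and return the 4x4 bits.

    Returns None when the black border test fails.
    """
    src = np.array([[0, 0], [6, 0], [6, 6], [0, 6]], dtype=float)
    tf = _estimate_projective(src, quad)
    if tf is None:
        return None
    # average a small patch within each cell (robust to noise and slight
    # quad misregistration, unlike a single centre sample)
    offs = np.array([[0.0, 0.0], [0.2, 0.0], [-0.2, 0.0], [0.0, 0.2], [0.0, -0.2]])
    ii, jj = np.meshgrid(np.arange(6) + 0.5, np.arange(6) + 0.5, indexing="ij")
    centres = np.column_stack([jj.ravel(), ii.ravel()])
    pts = (centres[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    vals = _sample(img, tf(pts).reshape(36, len(offs), 2)).mean(axis=1).reshape(6, 6)
    thr = 0.5 * (black + white)
    bits = (vals > thr).astype(np.uint8)
    border = np.concatenate([bits[0], bits[-1], bits[1:-1, 0], bits[1:-1, -1]])
    if border.any():
        return None
    return bits[1:-1, 1:-1]


def detect_aruco(frame: Frame, spec: MarkerSpec,
                 min_area: int = 1500, max_area_frac: float = 0.2,
                 refine: bool = True) -> list[ArUcoDetection]:
    """Detect and decode the marker's ArUco anchor squares in one frame.

    Returns only detections whose decoded ids belong to ``spec``; corner order
    is canonical (pattern top-left first, clockwise).  Callers treat a result
    with fewer than four detections as an occluded frame and skip it.
    """
    img = frame.pixels
    lo, hi = np.percentile(img, [2, 98])
    if hi - lo < 10:  # blank / featureless frame
        return []
    thr = 0.5 * (lo + hi)
    dark = img < thr
    labels, n = ndimage.label(dark)
    if n == 0:
        return []
    codes = spec.anchor_codes()
    detections: dict[int, ArUcoDetection] = {}
    max_area = max_area_frac * img.size
    slices = ndimage.find_objects(labels)
    areas = np.bincount(labels.ravel())
    for idx, sl in enumerate(slices, start=1):
        if sl is None or not (min_area <= areas[idx] <= max_area):
            continue
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        h, w = r1 - r0, c1 - c0
        if not (0.4 < h / max(w, 1) < 2.5):
            continue
        mask = labels == idx
        quad = _quad_from_mask(mask, (r0, c0, r1, c1))
        if quad is None:
            continue
        if refine:
            quad = _refine_quad_edges(img, quad)
        bits = _decode_bits(img, quad, black=lo, white=hi)
        if bits is None:
            continue
        for aid, code in codes.items():
            try:
                ordered = quad_canonical(quad, bits, code)
            except ValueError:
                continue
            if aid not in detections:
                detections[aid] = ArUcoDetection(aid, ordered)
            break
    return sorted(detections.values(), key=lambda d: d.id)


def quad_canonical(quad: np.ndarray, bits: np.ndarray, code: np.ndarray) -> np.ndarray:
    """Reorder a decoded quad so corner 0 is the code pattern's top-left.

    The decoder sampled cells with ``quad[0]`` as grid origin.  If the sampled
    bits match the code after ``r`` clockwise quarter-turns
    (``np.rot90(bits, -r) == code``) then the observed pattern is the code
    rotated ``r`` quarter-turns counter-clockwise, so the pattern's top-left
    corner sits ``r`` steps backwards along the quad winding.
    """
    for r in range(4):
        if np.array_equal(np.rot90(bits, -r), code):
            return np.roll(quad, r, axis=0)
    raise ValueError("bits do not match code under any rotation")


# ---------------------------------------------------------------------------
# Homography rectification
# ---------------------------------------------------------------------------

@dataclass
class RectifiedMarker:
    """Marker face resampled onto a rectilinear grid.

    ``image[r, c]`` samples the marker at
    ``x = x0 + c * mm_per_px``, ``y = y0 - r * mm_per_px`` (row 0 is the top
    edge of the face, +Y in the marker frame).
    """

    image: np.ndarray
    mm_per_px: float
    x0: float
    y0: float
    transform: ProjectiveTransform  # marker mm -> source pixel

    def mm_to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy_mm)
        col = (xy[:, 0] - self.x0) / self.mm_per_px
        row = (self.y0 - xy[:, 1]) / self.mm_per_px
        return np.column_stack([col, row])

    def region_slice(self, region: tuple[float, float, float, float]):
        x0, y0, x1, y1 = region
        (c0, r1), (c1, r0) = self.mm_to_px(np.array([[x0, y0], [x1, y1]]))
        return slice(int(round(r0)), int(round(r1))), slice(int(round(c0)), int(round(c1)))


def anchor_correspondences(detections: list[ArUcoDetection], spec: MarkerSpec
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Matched (marker mm, pixel) corner arrays for all detected anchors."""
    mm, px = [], []
    for det in detections:
        anchor = spec.anchor_by_id(det.id)
        mm.append(anchor.corners)
        px.append(det.corners)
    return np.vstack(mm), np.vstack(px)


def marker_homography(detections: list[ArUcoDetection], spec: MarkerSpec
                      ) -> ProjectiveTransform:
    """Least-squares homography mapping marker-frame mm to source pixels."""
    if len(detections) < 4:
        raise OcclusionError(
            f"need 4 anchor detections for rectification, got {len(detections)}")
    mm, px = anchor_correspondences(detections, spec)
    tf = _estimate_projective(mm, px)
    if (tf is None or not np.all(np.isfinite(tf.params))
            or np.linalg.cond(tf.params) > 1e8):
        raise ValueError("degenerate homography (collinear or coincident corners)")
    return tf


def rectify_marker(frame: Frame, detections: list[ArUcoDetection], spec: MarkerSpec,
                   px_per_mm: float = 8.0) -> RectifiedMarker:
    """Resample the marker face to a rectilinear grid via the anchor homography."""
    tf = marker_homography(detections, spec)
    w, h = spec.face_size
    nx, ny = int(round(w * px_per_mm)), int(round(h * px_per_mm))
    mm_per_px = 1.0 / px_per_mm
    xs = -w / 2 + (np.arange(nx) + 0.5) * mm_per_px
    ys = h / 2 - (np.arange(ny) + 0.5) * mm_per_px
    gx, gy = np.meshgrid(xs, ys)
    src = tf(np.column_stack([gx.ravel(), gy.ravel()]))
    img = ndimage.map_coordinates(frame.pixels, [src[:, 1], src[:, 0]],
                                  order=1, mode="nearest").reshape(ny, nx)
    return RectifiedMarker(image=img, mm_per_px=mm_per_px,
                           x0=xs[0], y0=ys[0], transform=tf)


# ---------------------------------------------------------------------------
# Moiré profile extraction and phase fitting
# ---------------------------------------------------------------------------

def extract_moire_profile(rectified: RectifiedMarker, grating: MoireGratingPair,
                          spec: MarkerSpec) -> MoireProfile:
    """Average the grating region into a 1-D profile along its frequency axis.

    All pixel lines across the region's short edge are averaged (the mean of
    ``n`` grayscale lines); the profile runs along the long edge.
    """
    rows, cols = rectified.region_slice(grating.region)
    if (rows.start < 0 or cols.start < 0 or rows.stop > rectified.image.shape[0]
            or cols.stop > rectified.image.shape[1]):
        raise ValueError(f"grating region {grating.region} outside the rectified image")
    block = rectified.image[rows, cols]
    if grating.profile_axis == "x":
        values = block.mean(axis=0)
        n_lines = block.shape[0]
    else:
        values = block.mean(axis=1)
        n_lines = block.shape[1]
    # positions are centred on the strip so that the fitted phase parameter is
    # referenced at the region centre: phase differences between frames are
    # then insensitive to small frequency-estimate differences between fits
    positions = np.arange(values.size, dtype=float) - (values.size - 1) / 2.0
    return MoireProfile(values=values, positions=positions,
                        n_lines=n_lines, grating_ref=grating,
                        mm_per_px=rectified.mm_per_px)


def _wrap(phi):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


def fit_moire_phase(profile: MoireProfile, noise_floor: float = 1.0,
                    refine_omega: bool = True, tol: float = 1e-8,
                    max_iter: int = 200) -> PhaseMeasurement:
    """Least-squares fit of ``A*sin(omega*s - phi) + b`` to a moiré profile.

    The profile is mean-centred before fitting (with the offset left free) to
    decouple the offset from the amplitude.  ``omega`` is initialised at the
    nominal beat frequency and allowed to vary within +-25%; the phase is
    initialised by complex demodulation at the nominal frequency.  The result
    is canonical: amplitude > 0 and phase wrapped to (-pi, pi].
    """
    s = profile.positions
    y = profile.values - profile.values.mean()
    w0 = profile.expected_omega
    if w0 <= 0 or s.size < 8:
        raise PhaseFitError("profile too short or grating has no beat")
    if s.size * profile.mm_per_px * profile.grating_ref.beat_frequency < 2.0:
        raise PhaseFitError("profile spans fewer than 2 beat periods")

    # suppress the residual print-line carrier before fitting the beat: a
    # symmetric Gaussian kernel leaves the beat phase untouched while
    # attenuating the ~15x higher carrier frequency by many orders of
    # magnitude; the smeared ends are trimmed off and the (slight, known)
    # attenuation of the beat amplitude is compensated after the fit
    carrier_cpp = profile.grating_ref.f_front * profile.mm_per_px
    smooth_sigma = 0.0
    if carrier_cpp < 0.45:  # carrier actually representable on this grid
        sigma = 0.8 / max(carrier_cpp, 1e-6)
        if sigma > 0.5:
            smooth_sigma = sigma
            y = ndimage.gaussian_filter1d(y, sigma, mode="nearest")
            trim = int(np.ceil(3 * sigma))
            if s.size > 2 * trim + 8:
                s = s[trim:-trim]
                y = y[trim:-trim]

    # linear solve for the quadrature amplitudes at fixed omega
    def lin_fit(w):
        M = np.column_stack([np.sin(w * s), np.cos(w * s), np.ones_like(s)])
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        return coef, M

    coef0, M0 = lin_fit(w0)
    a, c, b0 = coef0
    amp0 = float(np.hypot(a, c))
    noise = float(np.std(y - M0 @ coef0))
    low_conf = amp0 < max(noise_floor, 3.0 * noise / np.sqrt(s.size / 2))
    phi0 = float(-np.arctan2(c, a))

    if low_conf:
        fitted = M0 @ coef0 + profile.values.mean()
        return PhaseMeasurement(amplitude=amp0, omega=w0, phase=_wrap(phi0),
                                offset=float(b0 + profile.values.mean()),
                                residual_rms=noise, fitted=fitted, low_confidence=True)

    def model(p):
        A, w, phi, b = p
        return A * np.sin(w * s - phi) + b

    p0 = np.array([amp0, w0, phi0, b0])
    if refine_omega:
        res = optimize.least_squares(
            lambda p: model(p) - y, p0,
            bounds=([0.0, 0.75 * w0, -2 * np.pi, -np.inf],
                    [np.inf, 1.25 * w0, 2 * np.pi, np.inf]),
            xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iter * 4)
        if not res.success and res.status <= 0:
            raise PhaseFitError(
                f"sinusoid fit did not converge: {res.message}",
                residual_rms=float(np.sqrt(np.mean(res.fun ** 2))))
        A, w, phi, b = res.x
        residual = float(np.sqrt(np.mean(res.fun ** 2)))
    else:
        A, w, phi, b = p0
        residual = noise
    if A < 0:
        A, phi = -A, phi + np.pi
    if smooth_sigma:
        A = A / np.exp(-0.5 * (w * smooth_sigma) ** 2)
    fitted = A * np.sin(w * s - phi) + b + profile.values.mean()
    return PhaseMeasurement(amplitude=float(A), omega=float(w), phase=float(_wrap(phi)),
                            offset=float(b + profile.values.mean()),
                            residual_rms=residual, fitted=fitted)


def through_plane_rotation(current: tuple[PhaseMeasurement, PhaseMeasurement],
                           reference: tuple[PhaseMeasurement, PhaseMeasurement],
                           gratings: tuple[MoireGratingPair, MoireGratingPair],
                           phase_sign: float = 1.0) -> float:
    """Fuse fine and coarse phase shifts into one through-plane rotation (degrees).

    The coarse channel converts its wrapped phase difference directly to an
    unambiguous angle; the fine channel then selects the 2*pi wrap count that
    brings its (far more sensitive) angle estimate closest to the coarse one.

    ``phase_sign`` maps the fitted-phase sign convention onto the rotation
    sign convention; it is a property of the marker layout and profile
    direction and is fixed by the renderer's geometry.
    """
    fine_cur, coarse_cur = current
    fine_ref, coarse_ref = reference
    fine_g, coarse_g = gratings
    dphi_fine = phase_sign * _wrap(fine_cur.phase - fine_ref.phase)
    dphi_coarse = phase_sign * _wrap(coarse_cur.phase - coarse_ref.phase)
    # joint brute force over wrap counts of both channels (the coarse channel
    # itself wraps beyond half its wrap rotation); the pair with the smallest
    # fine/coarse mismatch identifies the physical rotation
    theta_coarse = rotation_from_phase(
        dphi_coarse + 2.0 * np.pi * np.arange(-1, 2), coarse_g)
    theta_fine = rotation_from_phase(
        dphi_fine + 2.0 * np.pi * np.arange(-4, 5), fine_g)
    mismatch = np.abs(theta_fine[:, None] - theta_coarse[None, :])
    kf, kc = np.unravel_index(np.argmin(mismatch), mismatch.shape)
    # consistent channels agree to within measurement noise; a mismatch of a
    # sizeable fraction of the fine wrap flags inconsistent measurements
    if mismatch[kf, kc] > 0.25 * rotation_from_phase(2.0 * np.pi, fine_g):
        raise ValueError(
            f"fine/coarse channels disagree: fine {theta_fine[kf]:.3f} deg vs "
            f"coarse {theta_coarse[kc]:.3f} deg")
    return float(theta_fine[kf])


#: Mapping from the fitted beat-phase sign convention to the rotation sign
#: convention of the marker frame.  Fixed by the marker layout (profile
#: directions +X / -Y of the rectified grid) and by the far layer carrying
#: the higher-frequency print; verified against renderer ground truth.
DEFAULT_PHASE_SIGNS = {"pitch": -1.0, "yaw": -1.0}


# ---------------------------------------------------------------------------
# Per-frame orchestration
# ---------------------------------------------------------------------------

@dataclass
class FrameAnalysis:
    """Phase measurements for all four grating pairs of one frame."""

    occluded: bool
    detections: list[ArUcoDetection] = field(default_factory=list)
    rectified: RectifiedMarker | None = None
    phases: dict[tuple[str, str], PhaseMeasurement] = field(default_factory=dict)


def analyse_frame(frame: Frame, spec: MarkerSpec, px_per_mm: float = 8.0,
                  refine_omega: bool = True) -> FrameAnalysis:
    """Run anchor detection, rectification and phase fitting for one frame."""
    detections = detect_aruco(frame, spec)
    if len(detections) < 4:
        return FrameAnalysis(occluded=True, detections=detections)
    rect = rectify_marker(frame, detections, spec, px_per_mm=px_per_mm)
    phases = {}
    for g in spec.gratings:
        prof = extract_moire_profile(rect, g, spec)
        phases[(g.axis, g.grade)] = fit_moire_phase(prof, refine_omega=refine_omega)
    return FrameAnalysis(occluded=False, detections=detections,
                         rectified=rect, phases=phases)


def rotations_from_analysis(current: FrameAnalysis, reference: FrameAnalysis,
                            spec: MarkerSpec,
                            phase_signs: dict[str, float] | None = None
                            ) -> dict[str, float]:
    """Pitch and yaw angles (degrees) of ``current`` relative to ``reference``."""
    if current.occluded or reference.occluded:
        raise OcclusionError("cannot difference phases against an occluded frame")
    signs = phase_signs or DEFAULT_PHASE_SIGNS
    out = {}
    for axis in ("pitch", "yaw"):
        out[axis] = through_plane_rotation(
            (current.phases[(axis, "fine")], current.phases[(axis, "coarse")]),
            (reference.phases[(axis, "fine")], reference.phases[(axis, "coarse")]),
            (spec.grating(axis, "fine"), spec.grating(axis, "coarse")),
            phase_sign=signs[axis])
    return out
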