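"""Calibration-board corner detection in plain checkerboard images.

Saddle (X-) corners are located with a Harris response, assigned to the
board's inner-corner grid via a homography estimated from the four extreme
detections, and refined to sub-pixel accuracy with the gradient
saddle-point iteration shared with the marker pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import corner_harris, corner_peaks
from skimage.transform import ProjectiveTransform

from .calibration import CalibrationBoardSpec
from .corners import refine_checkerboard_corners

__all__ = ["detect_board_corners"]


def detect_board_corners(img: np.ndarray, board: CalibrationBoardSpec,
                         min_distance: int = 5) -> np.ndarray:
    """Detect the board's inner corners, returned in object-point order.

    Assumes the board is the dominant checkerboard in view (the synthetic
    calibration imagery); raises when the expected corner count cannot be
    recovered.
    """
    img = np.asarray(img, dtype=float)
    nr, nc = board.inner_corners
    n_expected = nr * nc
    response = corner_harris(img, sigma=2.0)
    peaks = corner_peaks(response, min_distance=min_distance,
                         num_peaks=int(n_expected * 1.5), threshold_rel=0.01)
    if len(peaks) < n_expected:
        raise ValueError(f"found {len(peaks)} corner candidates, need {n_expected}")
    pts = peaks[:, ::-1].astype(float)  # (x, y)

    # four extreme detections anchor a coarse grid homography
    obj = board.object_points()
    o_idx = [np.argmin(obj[:, 0] - obj[:, 1]), np.argmax(obj[:, 0] + obj[:, 1]),
             np.argmax(obj[:, 0] - obj[:, 1]), np.argmin(obj[:, 0] + obj[:, 1])]
    p_idx = [np.argmin(pts[:, 0] + pts[:, 1]), np.argmax(pts[:, 0] + pts[:, 1]),
             np.argmax(pts[:, 0] - pts[:, 1]), np.argmin(pts[:, 0] - pts[:, 1])]
    # object corners: careful pairing — image y grows downward, marker y up
    src = obj[[np.argmin(obj[:, 0] + -obj[:, 1]), np.argmax(obj[:, 0] - -obj[:, 1]),
               np.argmax(obj[:, 0] + -obj[:, 1]), np.argmin(obj[:, 0] - -obj[:, 1])]]
    dst = pts[[np.argmin(pts[:, 0] + pts[:, 1]), np.argmax(pts[:, 0] - pts[:, 1]),
               np.argmax(pts[:, 0] + pts[:, 1]), np.argmin(pts[:, 0] - pts[:, 1])]]
    from .detection import _estimate_projective

    tf = _estimate_projective(src, dst)
    if tf is None:
        raise ValueError("degenerate board geometry")
    predicted = tf(obj)
    # snap each prediction to the nearest Harris peak, then refine sub-pixel
    d2 = np.sum((predicted[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    nearest = np.argmin(d2, axis=1)
    if len(np.unique(nearest)) != n_expected:
        raise ValueError("could not uniquely assign detections to the corner grid")
    snapped = pts[nearest]
    return refine_checkerboard_corners(img, snapped)
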