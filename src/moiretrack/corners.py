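"""Sub-pixel checkerboard corner refinement.

Corner positions are first predicted by mapping the ideal checkerboard
geometry through the marker homography; each prediction is then refined with
the classic gradient saddle-point iteration: at a true corner every image
gradient in a neighbourhood is perpendicular to the vector from the corner
to that pixel, so the corner solves

    (sum_i w_i g_i g_i^T) q = sum_i w_i g_i g_i^T p_i

over window pixels p_i with gradients g_i and Gaussian weights w_i.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["refine_corner", "refine_checkerboard_corners"]


def _gradients(img: np.ndarray, sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-derivative gradient fields (smoother than finite differences,
    which bias the saddle solve toward the pixel grid)."""
    img = img.astype(np.float64)
    gx = ndimage.gaussian_filter(img, sigma, order=(0, 1))
    gy = ndimage.gaussian_filter(img, sigma, order=(1, 0))
    return gx, gy


def refine_corner(gx: np.ndarray, gy: np.ndarray, xy: np.ndarray,
                  half_window: int = 5, iterations: int = 5,
                  sigma: float | None = None) -> np.ndarray:
    """Refine one corner prediction ``xy`` on precomputed gradient fields."""
    h, w = gx.shape
    offs = np.arange(-half_window, half_window + 1, dtype=float)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    sigma = sigma or half_window / 2.0
    wgt = np.exp(-(ox ** 2 + oy ** 2) / (2 * sigma ** 2)).ravel()
    q = np.asarray(xy, dtype=float).copy()
    for _ in range(iterations):
        px = q[0] + ox.ravel()
        py = q[1] + oy.ravel()
        if (px.min() < 1 or py.min() < 1 or px.max() > w - 2 or py.max() > h - 2):
            return q  # too close to the border to refine
        gxs = ndimage.map_coordinates(gx, [py, px], order=1)
        gys = ndimage.map_coordinates(gy, [py, px], order=1)
        gxx = np.sum(wgt * gxs * gxs)
        gyy = np.sum(wgt * gys * gys)
        gxy = np.sum(wgt * gxs * gys)
        bx = np.sum(wgt * (gxs * gxs * px + gxs * gys * py))
        by = np.sum(wgt * (gxs * gys * px + gys * gys * py))
        A = np.array([[gxx, gxy], [gxy, gyy]])
        if np.abs(np.linalg.det(A)) < 1e-12:
            return q
        q_new = np.linalg.solve(A, [bx, by])
        if np.linalg.norm(q_new - q) < 1e-4:
            q = q_new
            break
        if np.linalg.norm(q_new - xy) > 2 * half_window:
            return q  # diverged away from the prediction; keep the last stable point
        q = q_new
    return q


def refine_checkerboard_corners(img: np.ndarray, predicted_px: np.ndarray,
                                half_window: int = 5, iterations: int = 5) -> np.ndarray:
    """Refine an (N, 2) array of predicted corner pixel positions."""
    gx, gy = _gradients(np.asarray(img, dtype=np.float64))
    return np.array([refine_corner(gx, gy, p, half_window, iterations)
                     for p in np.atleast_2d(predicted_px)])
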