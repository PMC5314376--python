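"""Canonical head feature maps and the binary map distance dF.

Each detected head is cut out as a square patch, binarised with Otsu's
threshold (the head has strong contrast against the water), oriented by
PCA on the foreground pixel coordinates, and rotated so the head points
to the right (0 degrees).  The resulting 65x65 grayscale map is the
fish's "identification photo"; its binary version is what inter-frame
matching compares.

Coordinates follow image convention: origin top-left, x rightward,
y downward; angles are measured in degrees from +x toward +y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .blob import HeadDetection
from .config import TrackerConfig


@dataclass
class HeadFeatureMap:
    gray: np.ndarray            # (65, 65) float
    binary: np.ndarray          # (65, 65) uint8 in {0, 1}; 1 = fish
    theta: float                # head orientation in the source frame, degrees
    threshold: float            # Otsu threshold used for both binarisations
    source: Optional[HeadDetection] = None


class DegeneratePatchError(ValueError):
    """Raised when a patch cannot be binarised or oriented."""


def extract_patch(
    frame: np.ndarray, x: float, y: float, halfside: int
) -> tuple[np.ndarray, np.ndarray]:
    """Square ``(2*halfside+1)`` patch centred on (x, y).

    Out-of-frame pixels are filled with the frame's median intensity
    (the water background dominates) and flagged in the validity mask.
    """
    if halfside < 1:
        raise ValueError("halfside must be >= 1")
    cx, cy = int(round(x)), int(round(y))
    side = 2 * halfside + 1
    h, w = frame.shape
    patch = np.full((side, side), np.median(frame), dtype=frame.dtype)
    mask = np.zeros((side, side), bool)
    y0, y1 = cy - halfside, cy + halfside + 1
    x0, x1 = cx - halfside, cx + halfside + 1
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    if sy0 < sy1 and sx0 < sx1:
        patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = frame[sy0:sy1, sx0:sx1]
        mask[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = True
    return patch, mask


def binarize_otsu(patch: np.ndarray, dark_foreground: bool = True) -> tuple[np.ndarray, float]:
    """Otsu binarisation; foreground (1) is the dark side by default."""
    if np.ptp(patch) == 0:
        raise DegeneratePatchError("degenerate patch: constant intensity")
    t = float(threshold_otsu(np.asarray(patch)))
    # skimage's convention puts the threshold bin itself on the dark side
    binary = (patch <= t) if dark_foreground else (patch > t)
    return binary.astype(np.uint8), t


def head_orientation_pca(binary: np.ndarray, gray: np.ndarray | None = None) -> float:
    """Orientation of the binarised head via PCA of foreground coordinates.

    Returns the direction of the leading principal axis in degrees
    [0, 360).  The 180-degree ambiguity of the axis is resolved toward
    the darker half of the patch (the snout side), split by the minor
    axis through the centroid; without a gray patch the axis direction
    in [0, 180) is returned.
    """
    ys, xs = np.nonzero(binary)
    if xs.size < 3:
        raise DegeneratePatchError("fewer than 3 foreground pixels")
    coords = np.stack([xs, ys]).astype(float)
    coords -= coords.mean(axis=1, keepdims=True)
    cov = coords @ coords.T / xs.size
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]  # (ux, uy), unit
    if gray is not None:
        proj = u @ coords
        pos, neg = proj > 0, proj < 0
        if pos.any() and neg.any():
            vals = gray[ys, xs].astype(float)
            if vals[pos].mean() > vals[neg].mean():
                u = -u
    theta = float(np.degrees(np.arctan2(u[1], u[0])) % 360.0)
    if gray is None:
        theta %= 180.0
    return theta


def central_component(binary: np.ndarray, close_radius: int = 3) -> np.ndarray:
    """Foreground connected component under the patch centre.

    Orientation estimation must not be polluted by a second fish whose
    body reaches into the patch; after a small binary closing (to bridge
    texture holes) only the component containing the centre pixel is
    kept.  Falls back to the full foreground if the centre is empty.
    """
    closed = ndimage.binary_closing(binary.astype(bool), structure=np.ones((2 * close_radius + 1,) * 2))
    labels, _ = ndimage.label(closed)
    cy, cx = binary.shape[0] // 2, binary.shape[1] // 2
    lab = labels[cy, cx]
    if lab == 0:
        ys, xs = np.nonzero(closed)
        if xs.size == 0:
            return binary
        d2 = (ys - cy) ** 2 + (xs - cx) ** 2
        lab = labels[ys[np.argmin(d2)], xs[np.argmin(d2)]]
    return (binary.astype(bool) & (labels == lab)).astype(np.uint8)


def rotate_patch(patch: np.ndarray, theta: float) -> np.ndarray:
    """Rotate the patch content by ``-theta`` about its centre.

    A feature at direction ``theta`` from the centre ends up at 0 degrees
    (pointing right).  Bilinear interpolation, constant fill with the
    patch median.
    """
    # With y downward, a feature at image angle theta maps onto the
    # +x axis under scipy's rotate(angle=theta) convention.
    return ndimage.rotate(
        patch, angle=theta, reshape=False, order=1,
        mode="constant", cval=float(np.median(patch)),
    )


def central_crop(patch: np.ndarray, size: int) -> np.ndarray:
    h, w = patch.shape
    y0 = (h - size) // 2
    x0 = (w - size) // 2
    return patch[y0 : y0 + size, x0 : x0 + size]


def make_feature_map(
    frame: np.ndarray, det: HeadDetection, config: TrackerConfig
) -> HeadFeatureMap:
    """Extract, binarise, orient and canonicalise one head detection.

    The pre-rotation patch (halfside 46, 93x93) is large enough that the
    65x65 central crop never samples outside it for any rotation angle
    (65 * sqrt(2) ~ 92).  The rotated crop is re-binarised with the same
    Otsu threshold as the original patch.
    """
    patch, _ = extract_patch(frame, det.x, det.y, config.patch_halfside)
    binary, t = binarize_otsu(patch)
    theta = head_orientation_pca(central_component(binary), patch)
    # one bilinear warp: rotate by -theta about the sub-pixel head point
    # and crop to map_size, so canonical maps of the same fish stay
    # aligned to a fraction of a pixel across frames
    half = config.patch_halfside
    c = config.map_size // 2
    fy, fx = det.y - round(det.y), det.x - round(det.x)
    rad = np.radians(theta)
    cos_t, sin_t = np.cos(rad), np.sin(rad)
    jj, ii = np.meshgrid(np.arange(config.map_size) - c,
                         np.arange(config.map_size) - c, indexing="xy")
    src_x = half + fx + cos_t * jj - sin_t * ii
    src_y = half + fy + sin_t * jj + cos_t * ii
    gray = ndimage.map_coordinates(
        patch.astype(np.float32), [src_y, src_x], order=1,
        mode="constant", cval=float(np.median(patch)),
    )
    binary_map = central_component((gray <= t).astype(np.uint8))
    return HeadFeatureMap(gray=gray, binary=binary_map, theta=theta,
                          threshold=t, source=det)


def feature_distance(b1: np.ndarray, b2: np.ndarray) -> int:
    """dF: number of pixels where the two binary maps disagree."""
    if b1.shape != b2.shape:
        raise ValueError(f"shape mismatch: {b1.shape} vs {b2.shape}")
    return int(np.count_nonzero(b1 != b2))
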