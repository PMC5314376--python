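"""Scale-space determinant-of-Hessian detection of fish heads.

Seen from above, a fish head is a compact dark region on a light
background — a blob.  The detector convolves each frame with second-order
Gaussian derivatives over a ladder of scales, forms the scale-normalised
determinant of the Hessian

    doH(x, y; sigma) = sigma^4 * (L_xx * L_yy - L_xy^2),

and keeps strict local maxima of doH over the 3x3x3 (x, y, sigma)
neighbourhood.  Maxima are then filtered by blob scale and by the frame
intensity at the blob centre (heads are dark, so an intensity ceiling
supplies the polarity that doH itself cannot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import TrackerConfig

#: Geometric spacing of the scale ladder.
SIGMA_RATIO = 1.2


@dataclass(frozen=True)
class HeadDetection:
    """One candidate fish-head point: a blob in scale space."""

    frame: int
    x: float
    y: float
    sigma: float
    doh_score: float
    center_intensity: float
    near_border: bool = False


@dataclass
class ScaleSpaceStack:
    sigmas: np.ndarray          # (S,), strictly increasing
    l_xx: np.ndarray            # (S, H, W)
    l_xy: np.ndarray
    l_yy: np.ndarray
    doh: np.ndarray             # scale-normalised determinant of Hessian

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.sigmas) > 0):
            raise ValueError("sigmas must be strictly increasing")


def sigma_ladder(sigma_min: float, sigma_max: float, ratio: float = SIGMA_RATIO) -> np.ndarray:
    """Geometric scale ladder spanning [sigma_min, sigma_max], endpoints included."""
    sigmas = [sigma_min]
    while sigmas[-1] * ratio < sigma_max * (1 - 1e-9):
        sigmas.append(sigmas[-1] * ratio)
    if sigmas[-1] < sigma_max:
        sigmas.append(sigma_max)
    return np.asarray(sigmas)


def gaussian_derivative_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled 1-D Gaussian and its first/second derivatives.

    Radius ``int(4*sigma + 0.5)``.  The smoothing kernel is normalised to
    unit sum; the second-derivative kernel is bias-corrected to exact
    zero sum (truncation would otherwise leave a residual response on
    constant images); the first derivative is zero-sum by symmetry.
    """
    r = int(4 * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    d1 = -x / sigma**2 * g
    d2 = (x**2 - sigma**2) / sigma**4 * g
    d2 -= d2.mean()
    return g, d1, d2


def compute_scale_space(frame: np.ndarray, sigmas) -> ScaleSpaceStack:
    """Second-order Gaussian-derivative responses and doH per scale.

    Each derivative is scale-normalised by ``sigma^2`` (second order), so
    the determinant carries a ``sigma^4`` factor and blob responses are
    comparable across scales.  Separable convolutions, reflect boundary.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.size == 0 or not np.all(np.diff(sigmas) > 0) or sigmas[0] <= 0:
        raise ValueError("sigmas must be non-empty, positive and strictly increasing")
    img = frame.astype(np.float64)
    h, w = img.shape
    if min(h, w) < int(4 * sigmas[-1]) + 1:
        raise ValueError("frame smaller than the largest filter support")
    l_xx = np.empty((sigmas.size, h, w))
    l_xy = np.empty_like(l_xx)
    l_yy = np.empty_like(l_xx)
    conv = lambda a, k, axis: ndimage.correlate1d(a, k[::-1], axis=axis, mode="reflect")
    for i, s in enumerate(sigmas):
        g, d1, d2 = gaussian_derivative_kernels(s)
        norm = s * s
        l_xx[i] = norm * conv(conv(img, d2, 1), g, 0)
        l_xy[i] = norm * conv(conv(img, d1, 1), d1, 0)
        l_yy[i] = norm * conv(conv(img, g, 1), d2, 0)
    doh = l_xx * l_yy - l_xy**2
    return ScaleSpaceStack(sigmas, l_xx, l_xy, l_yy, doh)


def _subpixel_offset(layer: np.ndarray, yi: int, xi: int) -> tuple[float, float]:
    """Quadratic refinement of a grid maximum; offsets clipped to +-0.5 px."""
    h, w = layer.shape
    if not (0 < yi < h - 1 and 0 < xi < w - 1):
        return 0.0, 0.0
    def fit(m, c, p):  # 1-D parabola through three samples
        denom = m - 2 * c + p
        return 0.0 if denom == 0 else float(np.clip(0.5 * (m - p) / denom, -0.5, 0.5))
    xs = fit(layer[yi, xi - 1], layer[yi, xi], layer[yi, xi + 1])
    ys = fit(layer[yi - 1, xi], layer[yi, xi], layer[yi + 1, xi])
    return xs, ys


def find_blob_maxima(
    stack: ScaleSpaceStack,
    frame_img: np.ndarray,
    doh_threshold: float,
    frame_index: int = 0,
) -> list[HeadDetection]:
    """Strict 3x3x3 local maxima of doH with response >= threshold.

    Boundary sigma layers are compared against existing neighbours only.
    Each detection carries the maximising scale and the frame intensity
    at its centre.
    """
    doh = stack.doh
    # rank filter over the 3x3x3 neighbourhood; strictness is enforced by
    # requiring the centre to exceed the dilated map of its neighbours.
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    neighbour_max = ndimage.maximum_filter(doh, footprint=footprint, mode="nearest")
    is_max = (doh > neighbour_max) & (doh >= doh_threshold)
    dets = []
    h, w = frame_img.shape
    for si, yi, xi in zip(*np.nonzero(is_max)):
        sigma = float(stack.sigmas[si])
        border = min(xi, yi, w - 1 - xi, h - 1 - yi) < 2 * sigma
        xs, ys = _subpixel_offset(doh[si], yi, xi)
        dets.append(
            HeadDetection(
                frame=frame_index,
                x=float(xi) + xs,
                y=float(yi) + ys,
                sigma=sigma,
                doh_score=float(doh[si, yi, xi]),
                center_intensity=float(frame_img[yi, xi]),
                near_border=border,
            )
        )
    dets.sort(key=lambda d: (-d.doh_score, d.y, d.x))
    return dets


def filter_head_candidates(
    dets: list[HeadDetection], config: TrackerConfig
) -> list[HeadDetection]:
    """Keep in-range blobs and suppress near-duplicates.

    A detection survives if its scale lies in ``sigma_range`` and its
    centre intensity in ``intensity_range``; among survivors closer than
    the larger blob's scale, only the higher-scoring one is kept.
    """
    s_lo, s_hi = config.sigma_range
    i_lo, i_hi = config.intensity_range
    kept: list[HeadDetection] = []
    for d in sorted(dets, key=lambda d: -d.doh_score):
        if not (s_lo <= d.sigma <= s_hi and i_lo <= d.center_intensity <= i_hi):
            continue
        dup = any(
            (d.x - k.x) ** 2 + (d.y - k.y) ** 2 < max(d.sigma, k.sigma) ** 2
            for k in kept
        )
        if not dup:
            kept.append(d)
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


def detect_heads(
    frame_img: np.ndarray, config: TrackerConfig, frame_index: int = 0
) -> list[HeadDetection]:
    """Full per-frame head detection: scale space -> maxima -> filtering.

    The ladder extends one rung past each end of ``sigma_range`` so that
    blobs peaking at an endpoint scale are genuine interior maxima while
    out-of-range clutter peaks at a ladder scale that the filter rejects.
    """
    s_lo, s_hi = config.sigma_range
    sigmas = sigma_ladder(s_lo / SIGMA_RATIO, s_hi * SIGMA_RATIO)
    stack = compute_scale_space(frame_img, sigmas)
    dets = find_blob_maxima(stack, frame_img, config.doh_threshold, frame_index)
    return filter_head_candidates(dets, config)
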