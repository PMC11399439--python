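"""Spot detection: intensity image → per-channel particle coordinates.

A deliberately simple detector for isolated diffraction-limited spots:
Gaussian smoothing, local maxima above an absolute intensity threshold
with a minimum peak separation, and optional subpixel refinement by an
intensity-weighted centroid in a 3×3 window.  Matching distances are
continuous, so subpixel coordinates are the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .points import PointCloudSet


@dataclass
class DetectionParams:
    """Detector knobs.

    ``threshold`` is an absolute intensity on the *smoothed* image unless
    ``threshold_quantile`` is set, in which case that image quantile is
    used instead.  Separation is in pixels.
    """

    sigma: float = 0.8
    threshold: float = 20.0
    threshold_quantile: float | None = None
    min_separation: int = 2
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.min_separation < 1:
            raise ValueError("min peak separation must be >= 1 px")


def detect_spots(img: np.ndarray, params: DetectionParams | None = None
                 ) -> np.ndarray:
    """Detect spot centers in one channel image.

    Returns an ``(n, 2)`` array of (row, col) pixel coordinates, subpixel
    refined when requested.  An all-zero image yields an empty cloud.
    """
    if params is None:
        params = DetectionParams()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.any(img < 0):
        raise ValueError("intensity image must be nonnegative")
    smoothed = gaussian_filter(img, params.sigma) if params.sigma > 0 else img
    if params.threshold_quantile is not None:
        thr = float(np.quantile(smoothed, params.threshold_quantile))
    else:
        thr = params.threshold
    peaks = peak_local_max(smoothed, min_distance=params.min_separation,
                           threshold_abs=thr, exclude_border=False)
    if len(peaks) == 0 or not params.subpixel:
        return peaks.astype(float)
    refined = np.empty(peaks.shape, dtype=float)
    nrow, ncol = smoothed.shape
    for i, (r, c) in enumerate(peaks):
        r0, r1 = max(0, r - 1), min(nrow, r + 2)
        c0, c1 = max(0, c - 1), min(ncol, c + 2)
        window = smoothed[r0:r1, c0:c1]
        w = window - window.min()  # background-insensitive weights
        total = w.sum()
        if total <= 0:
            refined[i] = (r, c)
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        refined[i] = ((w * rr).sum() / total, (w * cc).sum() / total)
    return refined


def detect_spots_multichannel(images: list[np.ndarray],
                              params: DetectionParams | None = None
                              ) -> PointCloudSet:
    """Run the detector on every channel and bundle the clouds."""
    return PointCloudSet([detect_spots(img, params) for img in images],
                         unit="px")
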