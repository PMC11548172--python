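"""Post-processing of the denoised frame.

The refinement chain is: optional region-of-interest (ROI) masking to
isolate the specimen, a 3x3 median filter to knock out residual
impulses, and a percentile contrast stretch to [0, 1] computed inside
the ROI.  A Canny edge map can be produced as an optional extra output
layer; it is never fed back into the quality metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .image import Image

__all__ = ["RoiMask", "roi_mask", "apply_postprocessing", "edges"]


@dataclass(frozen=True)
class RoiMask:
    """Boolean specimen mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    method: str  # "otsu" or "fixed"


def roi_mask(img: Image, method: str = "otsu", threshold: float | None = None) -> RoiMask:
    """Derive a specimen mask by intensity thresholding.

    ``method="otsu"`` picks the 256-bin threshold maximizing
    inter-class variance; ``method="fixed"`` uses ``threshold``
    directly.  Pixels at or above the threshold are foreground, and
    only the largest connected component is kept (spurious bright
    speckles would otherwise enter the ROI).
    """
    px = img.pixels
    if method == "otsu":
        if np.ptp(px) == 0:
            raise ValueError("cannot derive an Otsu ROI from a constant image")
        thr = float(filters.threshold_otsu(px, nbins=256))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown ROI method {method!r}")
    fg = px >= thr
    labels, nlab = ndimage.label(fg)
    if nlab > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, nlab + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return RoiMask(mask=fg, threshold=thr, method=method)


def apply_postprocessing(
    img: Image,
    mask: RoiMask | None = None,
    p_low: float = 1.0,
    p_high: float = 99.0,
    median_kernel: int = 3,
) -> Image:
    """Refine a denoised frame: mask -> median filter -> contrast stretch.

    The stretch maps the ``[p_low, p_high]`` percentile window (taken
    inside the ROI when a mask is given, else over the whole frame) to
    [0, 1] and clips.  A degenerate window (both percentiles equal)
    skips the stretch with a warning rather than dividing by zero.
    """
    if not p_low < p_high:
        raise ValueError(f"need p_low < p_high, got ({p_low}, {p_high})")
    px = img.pixels
    if mask is not None:
        px = np.where(mask.mask, px, 0.0)
    px = ndimage.median_filter(px, size=median_kernel, mode="nearest")
    region = px[mask.mask] if mask is not None else px
    lo, hi = np.percentile(region, [p_low, p_high])
    if hi == lo:
        warnings.warn(
            "degenerate percentile window; returning median-filtered image unstretched",
            stacklevel=2,
        )
        return img.with_pixels(np.clip(px, 0.0, 1.0))
    out = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(out)


def edges(img: Image, low: float, high: float) -> np.ndarray:
    """Canny edge map (Gaussian sigma 1, Sobel gradients, hysteresis).

    ``low``/``high`` are the hysteresis thresholds on normalized
    gradient magnitude, ``0 <= low < high <= 1``.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"need 0 <= low < high <= 1, got ({low}, {high})")
    return feature.canny(
        img.pixels, sigma=1.0, low_threshold=low, high_threshold=high, use_quantiles=False
    )
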