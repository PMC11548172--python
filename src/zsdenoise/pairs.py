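"""Self-supervised training-pair construction.

From a single noisy frame ``I`` two corrupted renditions are built with
one seeded Gaussian noise field ``n``:

* rendition A = ``I + n``
* rendition B = ``I - n``  (the sign-inverted noise)

so that ``(A + B) / 2 == I`` holds exactly — the identity the test suite
uses as its oracle.  The construction refines the rounded renditions so
the identity is bit-exact wherever float64 permits; only pixels whose
noise draw exceeds roughly three times the pixel intensity (far outside
the default sigma of 0.05 on [0, 1] intensities) can retain a half-ulp
rounding residue, because the two renditions then live in a coarser
binade than the doubled source value.  No clipping is applied at pair
creation; clamping
to ``[0, 1]`` happens only when tensors are fed to the sigmoid-output
network.  Both renditions are then median-filtered (kernel 3 by
default) to suppress high-intensity salt-and-pepper impulses before
they serve as training input/target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image import Image

__all__ = ["NoisePair", "make_pair", "median_prefilter"]


@dataclass(frozen=True)
class NoisePair:
    """Two corrupted renditions of one frame plus the injected noise field."""

    a: Image
    b: Image
    noise: np.ndarray
    sigma: float
    seed: int
    filtered: bool = False


def make_pair(img: Image, sigma: float = 0.05, seed: int = 0) -> NoisePair:
    """Corrupt ``img`` into the (A, B) = (I + n, I - n) rendition pair.

    Parameters
    ----------
    img : Image
        Normalized frame (pixels in ``[0, 1]``).
    sigma : float
        Standard deviation of the injected zero-mean Gaussian noise, in
        normalized-intensity units.  The level is a pipeline choice, not
        a property of the camera; 0.05 is the default.
    seed : int
        Seeds the noise field; identical arguments give bit-identical
        pairs.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    n = rng.normal(0.0, sigma, size=img.shape) if sigma > 0 else np.zeros(img.shape)
    t = 2.0 * img.pixels  # exact: doubling never rounds
    a = img.pixels + n
    b = t - a
    # Fast2Sum-style refinement: where rounding made a + b miss 2I, the
    # residual t - b is exactly representable (Sterbenz) unless |n|
    # exceeds the pixel value several-fold, so nudging a by < 1 ulp of b
    # restores the exact inverted-noise identity a + b == 2I.
    a2 = t - b
    fixable = ((a + b) != t) & ((a2 + b) == t)
    a = np.where(fixable, a2, a)
    return NoisePair(
        a=img.with_pixels(a),
        b=img.with_pixels(b),
        noise=n,
        sigma=float(sigma),
        seed=int(seed),
    )


def median_prefilter(pair: NoisePair, kernel: int = 3) -> NoisePair:
    """Median-filter both renditions with a ``kernel x kernel`` window.

    Border pixels are handled by edge replication, which avoids the
    darkened borders a zero-padded median would produce on small
    frames.  The filtered renditions are the actual training
    input/target of the zero-shot denoiser.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"median kernel must be an odd integer >= 3, got {kernel}")
    filt = lambda px: ndimage.median_filter(px, size=kernel, mode="nearest")
    return replace(
        pair,
        a=pair.a.with_pixels(filt(pair.a.pixels)),
        b=pair.b.with_pixels(filt(pair.b.pixels)),
        filtered=True,
    )
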