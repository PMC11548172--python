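"""Image-quality metrics: PSNR, SSIM, RMSE and Fourier ring correlation.

PSNR, SSIM and RMSE quantify fidelity between two intensity rasters;
FRC estimates effective spatial resolution by correlating the two
images' Fourier spectra over concentric frequency rings and locating
the frequency where the correlation drops below a criterion (fixed 1/7
by default).

Two regimes are supported by :func:`report`: when a clean reference
exists (synthetic phantoms) metrics are computed against it; without
one (real microscope frames) the denoised output is compared against
the raw input — this measures fidelity-to-input, not fidelity-to-truth,
and the report labels which regime was used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .image import Image

__all__ = ["QualityReport", "FRCCurve", "rmse", "psnr", "ssim", "frc", "report"]

FRC_DEFAULT_THRESHOLD = 1.0 / 7.0


def _arr(x) -> np.ndarray:
    return x.pixels if isinstance(x, Image) else np.asarray(x, dtype=np.float64)


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = _arr(x), _arr(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    return xa, ya


# ------------------------------------------------------------------- scalars
def rmse(x, y) -> float:
    """Root mean square error, sqrt(mean((x - y)^2))."""
    xa, ya = _pair(x, y)
    return float(np.sqrt(np.mean((xa - ya) ** 2)))


def psnr(x, y, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10·log10(peak² / MSE).

    Identical images give ``+inf`` (zero error has no finite dB value).
    """
    if peak <= 0:
        raise ValueError(f"peak must be > 0, got {peak}")
    xa, ya = _pair(x, y)
    mse = float(np.mean((xa - ya) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * np.log10(peak * peak / mse))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2.0
    coords = np.arange(size) - half
    g = np.exp(-(coords**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(
    x,
    y,
    peak: float = 1.0,
    window_size: int = 11,
    window_sigma: float = 1.5,
) -> float:
    """Mean local structural similarity index.

    Local statistics are taken under a normalized Gaussian window
    (11 x 11, sigma 1.5) over every fully interior ("valid") window
    position, with the canonical stabilizers C1 = (0.01·peak)²,
    C2 = (0.03·peak)².  Symmetric in its arguments.
    """
    xa, ya = _pair(x, y)
    if min(xa.shape) < window_size:
        raise ValueError(
            f"image shape {xa.shape} smaller than the {window_size}-pixel SSIM window; "
            "use a smaller window_size"
        )
    w = _gaussian_window(window_size, window_sigma)
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    conv = lambda im: fftconvolve(im, w, mode="valid")
    mux, muy = conv(xa), conv(ya)
    sxx = conv(xa * xa) - mux * mux
    syy = conv(ya * ya) - muy * muy
    sxy = conv(xa * ya) - mux * muy
    num = (2 * mux * muy + c1) * (2 * sxy + c2)
    den = (mux * mux + muy * muy + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


# ----------------------------------------------------------------------- FRC
@dataclass(frozen=True)
class FRCCurve:
    """Per-ring Fourier correlation with the threshold-crossing cutoff."""

    ring_radii: np.ndarray       # cycles/pixel, ascending, <= 0.5
    correlation: np.ndarray
    threshold: float
    cutoff_frequency: float      # cycles/pixel

    def to_rows(self) -> list[tuple[float, float]]:
        return list(zip(self.ring_radii.tolist(), self.correlation.tolist()))


def _center_crop_square(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    s = min(h, w)
    top, left = (h - s) // 2, (w - s) // 2
    return a[top : top + s, left : left + s]


def frc(x, y, threshold: float = FRC_DEFAULT_THRESHOLD) -> FRCCurve:
    """Fourier ring correlation between two images.

    Rings are single-frequency-bin annuli of the discrete Fourier
    transforms; ring k collects frequencies with |f| rounding to k/N
    cycles/pixel, up to Nyquist (0.5).  The cutoff is the first
    crossing below ``threshold``, linearly interpolated between ring
    centres; a curve that never crosses reports the Nyquist frequency.
    """
    xa, ya = _pair(x, y)
    xa, ya = _center_crop_square(xa), _center_crop_square(ya)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("FRC undefined for a constant image (zero spectrum off DC)")
    n = xa.shape[0]
    f1 = np.fft.fft2(xa)
    f2 = np.fft.fft2(ya)
    fy = np.fft.fftfreq(n)
    r = np.hypot(fy[:, None], fy[None, :])
    ring = np.rint(r * n).astype(int)
    kmax = n // 2
    keep = ring <= kmax
    num = np.bincount(ring[keep], weights=(f1 * np.conj(f2)).real[keep], minlength=kmax + 1)
    d1 = np.bincount(ring[keep], weights=(np.abs(f1) ** 2)[keep], minlength=kmax + 1)
    d2 = np.bincount(ring[keep], weights=(np.abs(f2) ** 2)[keep], minlength=kmax + 1)
    denom = np.sqrt(d1 * d2)
    corr = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    radii = np.arange(kmax + 1) / n

    cutoff = radii[-1]
    below = np.nonzero(corr < threshold)[0]
    if below.size:
        k = below[0]
        if k == 0:
            cutoff = 0.0
        else:
            c0, c1_ = corr[k - 1], corr[k]
            frac = (c0 - threshold) / (c0 - c1_) if c0 != c1_ else 0.0
            cutoff = float(radii[k - 1] + frac * (radii[k] - radii[k - 1]))
    return FRCCurve(
        ring_radii=radii,
        correlation=corr,
        threshold=float(threshold),
        cutoff_frequency=float(cutoff),
    )


# -------------------------------------------------------------------- report
@dataclass(frozen=True)
class QualityReport:
    """Scalar metric bundle plus the FRC curve and the regime used."""

    psnr_db: float
    ssim: float
    rmse: float
    peak: float
    regime: str                    # "reference" or "reference-free"
    frc_curve: FRCCurve | None = None

    def to_dict(self) -> dict:
        return {
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "rmse": self.rmse,
            "frc_cutoff_cycles_per_pixel": (
                self.frc_curve.cutoff_frequency if self.frc_curve is not None else None
            ),
            "regime": self.regime,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def report(
    raw,
    denoised,
    reference=None,
    *,
    peak: float = 1.0,
    with_frc: bool = True,
    frc_threshold: float = FRC_DEFAULT_THRESHOLD,
) -> QualityReport:
    """Evaluate a denoised frame.

    With a clean ``reference`` (synthetic regime) the denoised image is
    compared against it; without one (the real-data regime) it is
    compared against the raw input, which measures how much the output
    deviates from the observation rather than distance to truth.
    """
    target = raw if reference is None else reference
    regime = "reference-free" if reference is None else "reference"
    curve = frc(denoised, target, threshold=frc_threshold) if with_frc else None
    return QualityReport(
        psnr_db=psnr(denoised, target, peak=peak),
        ssim=ssim(denoised, target, peak=peak),
        rmse=rmse(denoised, target),
        peak=float(peak),
        regime=regime,
        frc_curve=curve,
    )
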