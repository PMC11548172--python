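"""Single-channel microscopy frame container and TIFF I/O.

All downstream stages (pair generation, network training, metrics,
post-processing) operate on floating-point intensities in ``[0, 1]``;
the sigmoid output layer of the denoiser requires that range.  The raw
camera range is retained in :class:`Image` metadata so results can be
mapped back to the source scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["Image", "read_tiff", "write_tiff", "normalize"]

_DTYPE_NAMES = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.uint16): "uint16",
}


@dataclass(frozen=True)
class Image:
    """A single-channel 2-D intensity raster.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of intensities (arbitrary units until
        :func:`normalize` maps them to ``[0, 1]``).
    source_dtype : str
        ``"uint8"``, ``"uint16"`` or ``"float"`` — the dtype of the data
        the frame was loaded from (or created with).
    source_range : tuple of float
        ``(min_raw, max_raw)`` of the original data, used by
        :func:`normalize` and for mapping results back to camera units.
    normalized : bool
        Whether ``pixels`` are already min–max scaled to ``[0, 1]``.
    """

    pixels: np.ndarray
    source_dtype: str = "float"
    source_range: tuple[float, float] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D single-channel frame, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"frame must be at least 8 x 8 pixels, got {px.shape}")
        object.__setattr__(self, "pixels", px)
        if self.source_range is None:
            rng = (float(px.min()), float(px.max())) if np.all(np.isfinite(px)) else (0.0, 0.0)
            object.__setattr__(self, "source_range", rng)
        lo, hi = self.source_range
        if lo > hi:
            raise ValueError(f"source_range min {lo} exceeds max {hi}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, *, normalized: bool | None = None) -> "Image":
        """Return a copy carrying the same source metadata but new pixels."""
        return replace(
            self,
            pixels=pixels,
            normalized=self.normalized if normalized is None else normalized,
        )


def read_tiff(path, *, stack: bool = False):
    """Read a grayscale TIFF as an :class:`Image` (or list for stacks).

    The first page is returned unless ``stack=True``, in which case every
    page becomes an independent 2-D frame in page order.  RGB input is
    rejected: channel collapse would silently alter intensities, so the
    caller must convert to single channel first.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise IOError(f"could not read TIFF {path!r}: {exc}") from exc
    if not pages:
        raise IOError(f"TIFF {path!r} contains no pages")

    def to_image(arr: np.ndarray) -> Image:
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            raise ValueError(
                f"{path!r} is an RGB(A) image; convert to single channel before loading"
            )
        if arr.ndim != 2:
            raise ValueError(f"{path!r}: expected 2-D grayscale page, got shape {arr.shape}")
        dtype = _DTYPE_NAMES.get(arr.dtype, "float")
        return Image(
            pixels=arr.astype(np.float64),
            source_dtype=dtype,
            source_range=(float(arr.min()), float(arr.max())),
        )

    if stack:
        return [to_image(p) for p in pages]
    return to_image(pages[0])


def normalize(img: Image) -> Image:
    """Min–max rescale to ``[0, 1]`` using the recorded source range.

    A zero-dynamic-range frame (``min_raw == max_raw``) maps to all
    zeros rather than NaN, keeping the pipeline total on degenerate
    inputs.  Non-finite pixels are an error — clamping them silently
    would hide acquisition faults.
    """
    px = img.pixels
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains NaN or Inf pixels; refusing to normalize")
    lo, hi = img.source_range
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return replace(img, pixels=out, normalized=True)


def write_tiff(img: Image, path, dtype: str = "float32") -> None:
    """Write a normalized image, quantizing to the requested dtype.

    ``float32`` output is bit-exact on round trip; integer dtypes
    quantize with at most half-an-LSB error after re-normalization.
    """
    px = img.pixels
    if px.min() < -1e-9 or px.max() > 1 + 1e-9:
        raise ValueError("write_tiff expects pixels in [0, 1]; normalize first")
    px = np.clip(px, 0.0, 1.0)
    if dtype == "uint8":
        data = np.round(px * 255.0).astype(np.uint8)
    elif dtype == "uint16":
        data = np.round(px * 65535.0).astype(np.uint16)
    elif dtype in ("float32", "float"):
        data = px.astype(np.float32)
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    try:
        tifffile.imwrite(path, data)
    except OSError as exc:
        raise IOError(f"could not write TIFF {path!r}: {exc}") from exc
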