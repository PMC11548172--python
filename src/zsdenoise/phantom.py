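"""Synthetic spheroid phantom generator with modality-flavoured noise.

Real light-sheet frames of multicellular spheroids are not bundled
with this package, so tests and benchmarks run on a synthetic stand-in:
a bright textured disk (a 2-D section through a spheroid) on a dark
background, with a known clean ground truth.  The noise model layers
the three corruptions seen in low-light camera data — signal-dependent
shot noise, additive Gaussian read noise, and salt-and-pepper impulse
noise — each at a controllable level.

The phantom emulates the gross geometry and texture of a spheroid
section, not its optics: there is no point-spread function, no light
sheet thickness, and no spectral structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .image import Image

__all__ = ["PhantomSpec", "NoiseSpec", "make_phantom", "corrupt", "NOISE_PRESETS"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture of the clean spheroid phantom.

    ``radius_fraction`` is the disk radius as a fraction of half the
    frame side; internal texture is smoothed seeded noise with
    correlation length ``texture_scale`` pixels and the given
    amplitude.  The disk rim is cosine-tapered over 3 px so the edge is
    band-limited rather than a hard step.
    """

    size: int = 256
    radius_fraction: float = 0.6
    core_intensity: float = 0.7
    background_intensity: float = 0.1
    texture_scale: float = 4.0
    texture_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.radius_fraction < 1:
            raise ValueError("radius_fraction must be in (0, 1)")
        if not 0 < self.core_intensity < 1:
            raise ValueError("core_intensity must be in (0, 1)")
        if not 0 <= self.background_intensity < self.core_intensity:
            raise ValueError("background_intensity must be in [0, core_intensity)")
        if self.size < 8:
            raise ValueError("size must be at least 8")
        if self.texture_scale <= 0 or self.texture_amplitude < 0:
            raise ValueError("texture_scale must be > 0 and texture_amplitude >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise: shot (Poisson), read (Gaussian), impulse.

    ``poisson_scale`` is the photon count corresponding to intensity
    1.0 (0 disables shot noise); ``gaussian_sigma`` is the read-noise
    std in normalized units; ``impulse_fraction`` of the pixels are
    replaced by 0 or 1 equiprobably.
    """

    gaussian_sigma: float = 0.1
    poisson_scale: float = 0.0
    impulse_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_scale < 0 or self.impulse_fraction < 0:
            raise ValueError("noise levels must be >= 0")
        if self.impulse_fraction > 0.5:
            raise ValueError("impulse_fraction must be <= 0.5")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NoiseSpec":
        return cls(**json.loads(text))


#: Documentation conveniences mirroring the three imaging channels of a
#: multimodal light-sheet setup; not calibrated to any instrument.
NOISE_PRESETS: dict[str, NoiseSpec] = {
    # elastic scattering at low laser power: read noise only
    "rayleigh": NoiseSpec(gaussian_sigma=0.05, poisson_scale=0.0, impulse_fraction=0.0),
    # weak inelastic signal: heavy read noise plus impulse pixels
    "raman": NoiseSpec(gaussian_sigma=0.15, poisson_scale=0.0, impulse_fraction=0.02),
    # photon-limited emission: shot-noise dominated
    "fluorescence": NoiseSpec(gaussian_sigma=0.02, poisson_scale=100.0, impulse_fraction=0.0),
}


def make_phantom(spec: PhantomSpec) -> Image:
    """Render the clean ground-truth phantom (deterministic per seed)."""
    n = spec.size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    d = np.hypot(yy - c, xx - c)
    radius = spec.radius_fraction * n / 2.0

    # cosine taper: 1 inside the disk, 0 beyond radius + 3 px
    w = np.zeros((n, n))
    w[d <= radius] = 1.0
    rim = (d > radius) & (d < radius + 3.0)
    w[rim] = 0.5 * (1.0 + np.cos(np.pi * (d[rim] - radius) / 3.0))

    texture = np.zeros((n, n))
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        raw = rng.standard_normal((n, n))
        smooth = ndimage.gaussian_filter(raw, sigma=spec.texture_scale)
        smooth /= smooth.std()
        texture = spec.texture_amplitude * smooth

    px = spec.background_intensity + w * (
        spec.core_intensity + texture - spec.background_intensity
    )
    px = np.clip(px, 0.0, 1.0)
    return Image(pixels=px, source_dtype="float", source_range=(0.0, 1.0), normalized=True)


def corrupt(img: Image, noise: NoiseSpec) -> Image:
    """Produce the noisy observation of a clean frame.

    Corruptions apply in physical order: shot noise on the signal, then
    additive read noise, then impulse pixels; the result is clipped to
    [0, 1] like a saturating detector.
    """
    rng = np.random.default_rng(noise.seed)
    px = img.pixels.copy()
    if noise.poisson_scale > 0:
        px = rng.poisson(np.clip(px, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        px = px + rng.normal(0.0, noise.gaussian_sigma, size=px.shape)
    if noise.impulse_fraction > 0:
        flat = rng.random(px.shape) < noise.impulse_fraction
        px[flat] = rng.integers(0, 2, size=int(flat.sum())).astype(float)
    return img.with_pixels(np.clip(px, 0.0, 1.0), normalized=True)
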