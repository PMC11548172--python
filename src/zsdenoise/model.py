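"""Zero-shot (per-image) self-supervised denoising model.

The denoiser is trained on the single frame it will denoise — no
external dataset, no pre-trained weights.  From the normalized raw
frame ``I`` a seeded Gaussian noise field ``n`` produces two corrupted
renditions ``A = I + n`` and ``B = I - n``; both are median-filtered
(kernel 3) and the network ``f_θ`` learns ``A → B`` by minimizing

    L(θ) = MSE(f_θ(A), B) + λ · mean(|∂x f_θ(A)| + |∂y f_θ(A)|)

with Adam (defaults: 100 epochs, batch size 1, learning rate 0.001,
λ = 0, i.e. pure MSE).  Because the injected noise is unpredictable
from ``A``, the network cannot fit it and converges toward the shared
underlying structure — the noise2noise principle.  The trained network
is then applied to the frame itself (by default after the same median
pre-filter, so inference matches the training distribution).

Two APIs are provided: a statsmodels-style :class:`ZeroShotDenoiser`
model object whose :meth:`~ZeroShotDenoiser.fit` returns a
:class:`ZeroShotResults`, and the functional layer
(:func:`build_model`, :func:`loss`, :func:`train_zero_shot`,
:func:`denoise`) the class wraps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Image, normalize, read_tiff
from .nn import Adam, UNet
from .pairs import NoisePair, make_pair, median_prefilter

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "ZeroShotDenoiser",
    "ZeroShotResults",
    "build_model",
    "loss",
    "train_zero_shot",
    "denoise",
]


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings; defaults follow the training recipe
    (Adam, 100 epochs, batch size 1, learning rate 0.001, pure MSE)."""

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 1
    lambda_reg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch traces of the objective and its two terms."""

    loss_per_epoch: np.ndarray = field(default_factory=lambda: np.empty(0))
    mse_per_epoch: np.ndarray = field(default_factory=lambda: np.empty(0))
    reg_per_epoch: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.loss_per_epoch)


# ----------------------------------------------------------------- objective
def _as_array(x) -> np.ndarray:
    return x.pixels if isinstance(x, Image) else np.asarray(x, dtype=np.float64)


def _tv_l1(pred: np.ndarray) -> tuple[float, np.ndarray]:
    """Anisotropic total variation and its (sub)gradient.

    Forward finite differences with edge replication: the replicated
    edge makes the last row/column differences zero, so the mean runs
    over the full H x W grid.
    """
    n = pred.size
    dx = np.diff(pred, axis=1)
    dy = np.diff(pred, axis=0)
    value = (np.abs(dx).sum() + np.abs(dy).sum()) / n
    grad = np.zeros_like(pred)
    sx = np.sign(dx)
    sy = np.sign(dy)
    grad[:, 1:] += sx
    grad[:, :-1] -= sx
    grad[1:, :] += sy
    grad[:-1, :] -= sy
    return float(value), grad / n


def loss(prediction, target, lambda_reg: float = 0.0) -> tuple[float, float, float]:
    """Evaluate L(θ) = MSE + λ·TV, returning ``(total, mse, reg)``."""
    p, t = _as_array(prediction), _as_array(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {t.shape}")
    mse = float(np.mean((p - t) ** 2))
    reg, _ = _tv_l1(p)
    return mse + lambda_reg * reg, mse, reg


def _loss_grad(pred: np.ndarray, target: np.ndarray, lambda_reg: float):
    mse = float(np.mean((pred - target) ** 2))
    reg, dreg = _tv_l1(pred)
    grad = 2.0 * (pred - target) / pred.size + lambda_reg * dreg
    return mse + lambda_reg * reg, mse, reg, grad


# ------------------------------------------------------------------ training
def build_model(
    input_shape: tuple[int, int],
    depth: int = 3,
    base_channels: int = 32,
    seed: int = 0,
) -> UNet:
    """Construct the encoder–decoder with deterministic initialization."""
    return UNet(input_shape, depth=depth, base_channels=base_channels, seed=seed)


def _padded(arr: np.ndarray, mult: int) -> np.ndarray:
    h, w = arr.shape
    ph, pw = (-h) % mult, (-w) % mult
    return np.pad(arr, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else arr


def train_zero_shot(
    pair: NoisePair,
    config: TrainingConfig,
    *,
    depth: int = 3,
    base_channels: int = 32,
    anchor: str = "pair",
    raw: Image | None = None,
    model: UNet | None = None,
) -> tuple[UNet, TrainingHistory]:
    """Train the denoiser on one (median-filtered) rendition pair.

    ``anchor`` selects the data term: ``"pair"`` (default) trains
    ``f(A) → B`` as the workflow prescribes; ``"raw"`` anchors the MSE
    to the raw frame itself (the literal reading of the printed
    objective), requiring ``raw``.
    """
    if anchor not in ("pair", "raw"):
        raise ValueError("anchor must be 'pair' or 'raw'")
    if anchor == "raw" and raw is None:
        raise ValueError("anchor='raw' requires the raw image")

    x = np.clip(pair.a.pixels, 0.0, 1.0)
    t = np.clip((raw.pixels if anchor == "raw" else pair.b.pixels), 0.0, 1.0)
    h, w = x.shape

    if model is None:
        model = build_model((h, w), depth=depth, base_channels=base_channels, seed=config.seed)
    mult = 2**model.depth
    xp = _padded(x, mult).astype(np.float32)[None]
    tp = _padded(t, mult)

    opt = Adam(model.layers, lr=config.learning_rate)
    hist = TrainingHistory(
        np.zeros(config.epochs), np.zeros(config.epochs), np.zeros(config.epochs)
    )
    for epoch in range(config.epochs):
        pred = model.forward(xp, training=True)[0].astype(np.float64)
        total, mse, reg, grad = _loss_grad(
            pred[:h, :w], tp[:h, :w], config.lambda_reg
        )
        hist.loss_per_epoch[epoch] = total
        hist.mse_per_epoch[epoch] = mse
        hist.reg_per_epoch[epoch] = reg
        dfull = np.zeros(pred.shape, dtype=np.float32)
        dfull[:h, :w] = grad
        model.zero_grads()
        model.backward(dfull[None])
        opt.step()
    return model, hist


def denoise(model: UNet, img: Image) -> Image:
    """Apply a trained network to a normalized frame.

    The input is clamped to ``[0, 1]`` before the forward pass (pair
    creation does not clip, so renditions can stray slightly outside);
    inference uses the normalization layers' running statistics, so the
    output is deterministic for a fixed model.
    """
    out = model.predict(np.clip(img.pixels, 0.0, 1.0))
    return img.with_pixels(out, normalized=True)


# --------------------------------------------------------- model-object API
class ZeroShotDenoiser:
    """Per-image self-supervised denoiser, statsmodels-style.

    Parameters
    ----------
    image : Image
        The normalized noisy frame to be denoised (pixels in [0, 1]).
    noise_sigma : float
        Std of the injected Gaussian noise used to build the training
        pair, in normalized-intensity units.
    median_kernel : int
        Window of the median pre-filter applied to both renditions.
    depth, base_channels : int
        Encoder–decoder size (levels, first-level feature maps).
    anchor : str
        ``"pair"`` (noise2noise, default) or ``"raw"`` data term.
    infer_on : str
        What the trained network sees at inference time:
        ``"filtered"`` (default) applies the same median pre-filter the
        training inputs received — the network never saw an unfiltered
        frame during training, and impulse pixels in a raw frame would
        pass straight through it — or ``"raw"`` for the unfiltered
        frame.
    seed : int
        Seeds both the noise field and the weight initialization.

    Examples
    --------
    >>> model = ZeroShotDenoiser(noisy_frame, noise_sigma=0.05, seed=0)
    >>> res = model.fit(epochs=50)
    >>> clean_estimate = res.denoise()
    """

    def __init__(
        self,
        image: Image,
        *,
        noise_sigma: float = 0.05,
        median_kernel: int = 3,
        depth: int = 3,
        base_channels: int = 32,
        anchor: str = "pair",
        infer_on: str = "filtered",
        seed: int = 0,
    ) -> None:
        px = image.pixels
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("image must be normalized to [0, 1]; call normalize() first")
        if infer_on not in ("filtered", "raw"):
            raise ValueError("infer_on must be 'filtered' or 'raw'")
        self.image = image
        self.noise_sigma = float(noise_sigma)
        self.median_kernel = int(median_kernel)
        self.depth = int(depth)
        self.base_channels = int(base_channels)
        self.anchor = anchor
        self.infer_on = infer_on
        self.seed = int(seed)

    @classmethod
    def from_tiff(cls, path, **kwargs) -> "ZeroShotDenoiser":
        """Load a frame from disk, normalize it, and build the model."""
        return cls(normalize(read_tiff(path)), **kwargs)

    def make_training_pair(self) -> NoisePair:
        """The median-filtered (A, B) pair the network trains on."""
        pair = make_pair(self.image, sigma=self.noise_sigma, seed=self.seed)
        return median_prefilter(pair, kernel=self.median_kernel)

    def fit(
        self,
        config: TrainingConfig | None = None,
        *,
        learning_rate: float = 0.001,
        epochs: int = 100,
        batch_size: int = 1,
        lambda_reg: float = 0.0,
    ) -> "ZeroShotResults":
        """Train the per-image network and return the fitted results."""
        if config is None:
            config = TrainingConfig(
                learning_rate=learning_rate,
                epochs=epochs,
                batch_size=batch_size,
                lambda_reg=lambda_reg,
                seed=self.seed,
            )
        pair = self.make_training_pair()
        net, history = train_zero_shot(
            pair,
            config,
            depth=self.depth,
            base_channels=self.base_channels,
            anchor=self.anchor,
            raw=self.image,
        )
        return ZeroShotResults(self, net, history, config, pair)


class ZeroShotResults:
    """Fitted zero-shot denoiser: trained weights, loss traces, inference."""

    def __init__(
        self,
        model: ZeroShotDenoiser,
        network: UNet,
        history: TrainingHistory,
        config: TrainingConfig,
        pair: NoisePair,
    ) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.config = config
        self.pair = pair

    def denoise(self, image: Image | None = None) -> Image:
        """Denoise a frame (default: the frame the model was fitted on).

        When the model was built with ``infer_on="filtered"`` (the
        default), the frame receives the same median pre-filter the
        training inputs did before the forward pass.
        """
        img = self.model.image if image is None else image
        if self.model.infer_on == "filtered":
            img = img.with_pixels(
                ndimage.median_filter(img.pixels, size=self.model.median_kernel, mode="nearest")
            )
        return denoise(self.network, img)

    def save(self, path) -> None:
        """Persist weights (.npz) and architecture sidecar (.json)."""
        self.network.save(path)

    def summary(self) -> str:
        """Human-readable fit report."""
        h = self.history
        buf = io.StringIO()
        line = "=" * 58
        buf.write(f"{line}\n{'Zero-Shot Denoiser Results':^58}\n{line}\n")
        rows = [
            ("Frame size", f"{self.model.image.height} x {self.model.image.width}"),
            ("Injected noise sigma", f"{self.model.noise_sigma:g}"),
            ("Median pre-filter", f"{self.model.median_kernel} x {self.model.median_kernel}"),
            ("Depth / base channels", f"{self.model.depth} / {self.model.base_channels}"),
            ("Trainable parameters", f"{self.network.num_parameters():,}"),
            ("Optimizer", "Adam"),
            ("Learning rate", f"{self.config.learning_rate:g}"),
            ("Epochs", f"{self.config.epochs}"),
            ("Batch size", f"{self.config.batch_size}"),
            ("Lambda (smoothness)", f"{self.config.lambda_reg:g}"),
            ("Seed", f"{self.config.seed}"),
        ]
        if len(h):
            rows += [
                ("Initial loss", f"{h.loss_per_epoch[0]:.6f}"),
                ("Final loss", f"{h.loss_per_epoch[-1]:.6f}"),
                ("Final MSE term", f"{h.mse_per_epoch[-1]:.6f}"),
                ("Final reg term", f"{h.reg_per_epoch[-1]:.6f}"),
            ]
        for k, v in rows:
            buf.write(f"{k:<28}{v:>30}\n")
        buf.write(line + "\n")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ZeroShotResults epochs={self.config.epochs} "
            f"final_loss={self.history.loss_per_epoch[-1]:.4g}>"
            if len(self.history)
            else "<ZeroShotResults (untrained)>"
        )
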