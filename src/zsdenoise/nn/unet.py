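"""Encoder–decoder denoising network with skip connections.

The encoder halves the spatial size per level with 2x2 max pooling and
doubles the channel count; the decoder mirrors it with nearest-neighbour
upsampling and convolutions, concatenating the matching encoder features
(skip connections) so high-resolution detail survives the bottleneck.
Every convolution is followed by batch normalization and ReLU except the
final 1x1 projection, whose sigmoid keeps the output in ``(0, 1)``.

Inputs whose sides are not multiples of ``2**depth`` are reflect-padded
before the forward pass and cropped back afterwards.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import BatchNorm2d, Conv2d, Layer, MaxPool2d, ReLU, Sigmoid, Upsample2d

__all__ = ["UNet"]


class _ConvBlock:
    """conv -> batchnorm -> relu."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator) -> None:
        self.conv = Conv2d(in_ch, out_ch, ksize, rng)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    @property
    def layers(self) -> list[Layer]:
        return [self.conv, self.bn, self.relu]


class UNet:
    """2-D convolutional encoder–decoder built for per-image training.

    Parameters
    ----------
    input_shape : tuple of int
        ``(height, width)`` the model is intended for; both sides must
        be at least ``2**depth`` so the bottleneck keeps a positive
        spatial extent.
    depth : int
        Number of pooling/upsampling levels.
    base_channels : int
        Feature maps at the first encoder level; doubled per level.
    seed : int
        Seeds the He-normal weight initialization deterministically.
    """

    def __init__(
        self,
        input_shape: tuple[int, int],
        depth: int = 3,
        base_channels: int = 32,
        seed: int = 0,
    ) -> None:
        h, w = input_shape
        if min(h, w) < 2**depth:
            raise ValueError(
                f"input shape {input_shape} smaller than 2**depth = {2**depth} in one axis"
            )
        self.input_shape = (int(h), int(w))
        self.depth = int(depth)
        self.base_channels = int(base_channels)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        chans = [base_channels * 2**l for l in range(depth)]

        self.enc_blocks: list[_ConvBlock] = []
        self.pools: list[MaxPool2d] = []
        in_ch = 1
        for c in chans:
            self.enc_blocks.append(_ConvBlock(in_ch, c, 3, rng))
            self.pools.append(MaxPool2d())
            in_ch = c
        self.bottleneck = _ConvBlock(in_ch, in_ch * 2, 3, rng)

        self.ups: list[Upsample2d] = []
        self.dec_pre: list[_ConvBlock] = []   # after upsampling, before the skip concat
        self.dec_post: list[_ConvBlock] = []  # fuses the concatenated skip features
        cur = in_ch * 2
        for c in reversed(chans):
            self.ups.append(Upsample2d())
            self.dec_pre.append(_ConvBlock(cur, c, 3, rng))
            self.dec_post.append(_ConvBlock(2 * c, c, 3, rng))
            cur = c
        self.final_conv = Conv2d(chans[0], 1, 1, rng)
        self.final_act = Sigmoid()
        self._skip_channels: list[int] = []

    # ------------------------------------------------------------------ layers
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            out += blk.layers + [pool]
        out += self.bottleneck.layers
        for up, pre, post in zip(self.ups, self.dec_pre, self.dec_post):
            out += [up] + pre.layers + post.layers
        out += [self.final_conv, self.final_act]
        return out

    def num_parameters(self) -> int:
        return sum(layer.num_parameters() for layer in self.layers)

    def zero_grads(self) -> None:
        for layer in self.layers:
            for k in layer.grads:
                layer.grads[k][...] = 0.0

    # ----------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map a ``(1, H, W)`` tensor to a ``(1, H, W)`` tensor in (0, 1)."""
        if x.ndim != 3 or x.shape[0] != 1:
            raise ValueError(f"expected (1, H, W) input, got {x.shape}")
        h, w = x.shape[1:]
        if (h % 2**self.depth) or (w % 2**self.depth):
            raise ValueError(
                f"spatial shape {(h, w)} not divisible by 2**depth = {2**self.depth}; "
                "use predict() which pads automatically"
            )
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = [s.shape[0] for s in skips]
        for up, pre, post, skip in zip(self.ups, self.dec_pre, self.dec_post, reversed(skips)):
            x = up.forward(x, training)
            x = pre.forward(x, training)
            x = np.concatenate([skip, x], axis=0)
            x = post.forward(x, training)
        x = self.final_conv.forward(x, training)
        return self.final_act.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients from d(loss)/d(output).

        Returns the gradient with respect to the network input.
        """
        g = self.final_conv.backward(self.final_act.backward(dy))
        skip_grads: list[np.ndarray] = []
        for up, pre, post, c_skip in zip(
            reversed(self.ups),
            reversed(self.dec_pre),
            reversed(self.dec_post),
            self._skip_channels,
        ):
            g = post.backward(g)
            skip_grads.append(g[:c_skip])
            g = pre.backward(g[c_skip:])
            g = up.backward(g)
        g = self.bottleneck.backward(g)
        # skip_grads were collected top level first (encoder level 0 first);
        # the encoder backward walks deepest level first, so reverse them
        for blk, pool, sg in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + sg
            g = blk.backward(g)
        return g

    # --------------------------------------------------------------- inference
    def predict(self, image: np.ndarray) -> np.ndarray:
        """Denoise a 2-D array, reflect-padding to the pooling granularity."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError(f"predict expects a 2-D frame, got shape {image.shape}")
        h, w = image.shape
        mult = 2**self.depth
        ph = (-h) % mult
        pw = (-w) % mult
        x = np.pad(image, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else image
        y = self.forward(x[None], training=False)[0]
        return y[:h, :w].astype(np.float64)

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        """Save weights as ``.npz`` plus a JSON sidecar of hyperparameters."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"{i}:{k}"] = v
            if isinstance(layer, BatchNorm2d):
                arrays[f"{i}:running_mean"] = layer.running_mean
                arrays[f"{i}:running_var"] = layer.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "input_shape": list(self.input_shape),
            "depth": self.depth,
            "base_channels": self.base_channels,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "UNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = cls(
            tuple(meta["input_shape"]),
            depth=meta["depth"],
            base_channels=meta["base_channels"],
            seed=meta["seed"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            for i, layer in enumerate(net.layers):
                for k in layer.params:
                    layer.params[k][...] = data[f"{i}:{k}"]
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = data[f"{i}:running_mean"]
                    layer.running_var[...] = data[f"{i}:running_var"]
        return net
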