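"""Configurable 3D encoder-decoder segmentation network.

Encoder levels: two (conv3 -> batch-norm -> ReLU) blocks, max-pool between
levels. Decoder: nearest x2 upsampling followed by a convolution, skip
concatenation, then two conv blocks. Output: 1-channel convolution +
sigmoid. Weights use Xavier initialization; biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import DTYPE, BatchNorm, Conv3d, MaxPool2, ReLU, Sigmoid, Upsample2


@dataclass
class NetConfig:
    levels: int = 2
    filters: tuple[int, ...] = (8, 16)
    kernel: int = 3
    alpha: float = 0.5
    beta: float | None = None  # defaults to 1 - alpha
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0
    init: str = "xavier"
    final_kernel: int = 1

    def __post_init__(self) -> None:
        if len(self.filters) != self.levels:
            raise ValueError("filters length must equal levels")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0,1]")
        if self.beta is None:
            self.beta = 1.0 - self.alpha
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0,1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.init != "xavier":
            raise ValueError("only xavier init is supported")


# replica of the published architecture; the printed total (855,111
# trainable parameters) cannot be confirmed from the text alone because the
# figure carrying the per-level filter counts is not machine-readable, so
# these counts are a best-effort stand-in and the equality check is
# expected to be unverifiable.
REPLICA_CONFIG = NetConfig(levels=3, filters=(32, 64, 128), epochs=100)


class _ConvBlock:
    def __init__(self, c_in, c_out, kernel, rng):
        self.layers = [Conv3d(c_in, c_out, kernel, rng), BatchNorm(c_out), ReLU()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """Encoder-decoder with skip concatenations; see module docstring."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = list(cfg.filters)
        self.enc: list[list[_ConvBlock]] = []
        self.pools: list[MaxPool2] = []
        c_in = 1
        for lvl in range(cfg.levels):
            self.enc.append([
                _ConvBlock(c_in, f[lvl], cfg.kernel, rng),
                _ConvBlock(f[lvl], f[lvl], cfg.kernel, rng),
            ])
            c_in = f[lvl]
            if lvl < cfg.levels - 1:
                self.pools.append(MaxPool2())
        self.dec: list[dict] = []
        for lvl in range(cfg.levels - 2, -1, -1):
            self.dec.append({
                "up": Upsample2(),
                "up_conv": _ConvBlock(c_in, f[lvl], cfg.kernel, rng),
                "blocks": [
                    _ConvBlock(2 * f[lvl], f[lvl], cfg.kernel, rng),
                    _ConvBlock(f[lvl], f[lvl], cfg.kernel, rng),
                ],
            })
            c_in = f[lvl]
        self.final = Conv3d(c_in, 1, cfg.final_kernel, rng)
        self.sigmoid = Sigmoid()

    # -- structure walking -------------------------------------------------
    def _blocks(self):
        for level in self.enc:
            yield from level
        for d in self.dec:
            yield d["up_conv"]
            yield from d["blocks"]

    def parameters(self):
        """Yield (qualified-name, value-array, grad-array)."""
        for bi, block in enumerate(self._blocks()):
            for li, layer in enumerate(block.layers):
                for name, v, g in layer.params():
                    yield f"block{bi}.l{li}.{name}", v, g
        for name, v, g in self.final.params():
            yield f"final.{name}", v, g

    def n_params(self) -> int:
        return sum(v.size for _, v, _ in self.parameters())

    # -- passes ------------------------------------------------------------
    def forward(self, x, training=False):
        """x: (B, side, side, side) or (B, side, side, side, 1)."""
        if x.ndim == 4:
            x = x[..., None]
        x = x.astype(DTYPE)
        skips = []
        for lvl, level in enumerate(self.enc):
            for block in level:
                x = block.forward(x, training)
            if lvl < len(self.enc) - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, training)
        self._skip_channels = []
        for d, skip in zip(self.dec, reversed(skips)):
            x = d["up"].forward(x, training)
            x = d["up_conv"].forward(x, training)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            for block in d["blocks"]:
                x = block.forward(x, training)
        x = self.final.forward(x, training)
        y = self.sigmoid.forward(x, training)
        return y[..., 0]

    def backward(self, dy):
        dy = dy[..., None].astype(DTYPE)
        dy = self.sigmoid.backward(dy)
        dy = self.final.backward(dy)
        dskips = []
        for d in reversed(self.dec):
            for block in reversed(d["blocks"]):
                dy = block.backward(dy)
            c_skip = self._skip_channels[self.dec.index(d)]
            dskip, dy = dy[..., :c_skip], dy[..., c_skip:]
            dskips.append(dskip)
            dy = d["up_conv"].backward(dy)
            dy = d["up"].backward(dy)
        for lvl in range(len(self.enc) - 1, -1, -1):
            if lvl < len(self.enc) - 1:
                dy = self.pools[lvl].backward(dy)
                # dskips were collected shallow-to-deep, i.e. dskips[lvl]
                dy = dy + dskips[lvl]
            for block in reversed(self.enc[lvl]):
                dy = block.backward(dy)
        return dy

    # -- inference helper --------------------------------------------------
    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Single z-scored patch (side^3) -> probability patch (side^3)."""
        return self.forward(patch[None], training=False)[0]

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: v.copy() for name, v, _ in self.parameters()}
        for bi, block in enumerate(self._blocks()):
            for li, layer in enumerate(block.layers):
                if isinstance(layer, BatchNorm):
                    out[f"block{bi}.l{li}.running_mean"] = layer.running_mean.copy()
                    out[f"block{bi}.l{li}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, v, _ in self.parameters():
            v[...] = state[name]
        for bi, block in enumerate(self._blocks()):
            for li, layer in enumerate(block.layers):
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = state[f"block{bi}.l{li}.running_mean"]
                    layer.running_var[...] = state[f"block{bi}.l{li}.running_var"]


def build_unet(cfg: NetConfig) -> tuple[UNet3D, int]:
    """Instantiate the network and report its trainable parameter count."""
    model = UNet3D(cfg)
    return model, model.n_params()
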