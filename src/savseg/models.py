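"""The three encoder–decoder segmentation architectures at configurable scale.

U-Net (symmetric encoder/decoder with skip concatenations), FC-DenseNet
(dense blocks with within-block concatenation on both paths), and
DeepLabv3+ (encoder with atrous spatial pyramid pooling plus a decoder that
fuses a low-level feature map).  All models map an (N, 3, T, T) input to
(N, n_classes, T, T) logits; ``softmax`` over the class axis yields per-pixel
probability simplexes.

The full-size configurations used in GPU studies are presets
(``PRESETS``); the default scale is small enough to train on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autodiff import (Tensor, concat, global_avg_pool, broadcast_spatial,
                          maxpool2d, relu, softmax, upsample_nearest)
from .nn.layers import Conv2d, ConvRelu, Module

ARCHITECTURES = ("unet", "fc_densenet", "deeplabv3plus")


def image_to_input(image: np.ndarray) -> np.ndarray:
    """(H,W,3) uint8 image -> zero-centred (3,H,W) float in [-0.5, 0.5]."""
    return np.asarray(image, dtype=np.float64).transpose(2, 0, 1) / 255.0 - 0.5


@dataclass
class ModelConfig:
    architecture: str = "unet"
    n_classes: int = 2
    depth: int = 2
    base_width: int = 8
    atrous_rates: tuple = (1, 2, 4)          # deeplabv3plus only
    growth_rate: int = 4                     # fc_densenet only
    block_layers: int = 2                    # fc_densenet only
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {ARCHITECTURES}")
        if self.n_classes < 1 or self.depth < 1 or self.base_width < 1:
            raise ValueError("n_classes, depth and base_width must be positive")


# Scales matching the study's full-size training runs; not intended for CPU use.
PRESETS = {
    "unet-full": ModelConfig("unet", depth=4, base_width=64),
    "fc_densenet-full": ModelConfig("fc_densenet", depth=4, base_width=48,
                                    growth_rate=16, block_layers=4),
    "deeplabv3plus-full": ModelConfig("deeplabv3plus", depth=4, base_width=64,
                                      atrous_rates=(1, 6, 12, 18)),
}


class SegmentationModel(Module):
    """Common surface: forward to logits, predict hard labels."""

    config: ModelConfig

    def _check_input(self, x: Tensor):
        n, c, h, w = x.data.shape
        if c != 3:
            raise ValueError(f"expected 3 input channels, got {c}")
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"tile size {h}x{w} not divisible by 2^depth = {div}")

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        self._check_input(x)
        return self.forward(x)

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """(H,W,3) uint8/float image -> (K,H,W) softmax probabilities."""
        x = Tensor(image_to_input(image)[None])
        logits = self(x)
        return softmax(logits.data, axis=1)[0]

    def predict(self, image: np.ndarray) -> np.ndarray:
        """(H,W,3) image -> (H,W) int class-id mask."""
        return self.predict_probs(image).argmax(axis=0)


class UNet(SegmentationModel):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        self.enc = []
        c_in = 3
        for level in range(config.depth):
            c_out = w * 2 ** level
            self.enc.append([ConvRelu(c_in, c_out, 3, rng),
                             ConvRelu(c_out, c_out, 3, rng)])
            c_in = c_out
        c_mid = w * 2 ** config.depth
        self.mid = [ConvRelu(c_in, c_mid, 3, rng), ConvRelu(c_mid, c_mid, 3, rng)]
        self.dec = []
        c_in = c_mid
        for level in reversed(range(config.depth)):
            c_skip = w * 2 ** level
            self.dec.append([ConvRelu(c_in, c_skip, 3, rng),       # post-upsample
                             ConvRelu(c_skip * 2, c_skip, 3, rng),  # after concat
                             ConvRelu(c_skip, c_skip, 3, rng)])
            c_in = c_skip
        self.head = Conv2d(c_in, config.n_classes, 1, rng)

    def forward(self, x):
        skips = []
        h = x
        for block in self.enc:
            for layer in block:
                h = layer(h)
            skips.append(h)
            h = maxpool2d(h)
        for layer in self.mid:
            h = layer(h)
        for block, skip in zip(self.dec, reversed(skips)):
            h = block[0](upsample_nearest(h, 2))
            h = block[1](concat([h, skip]))
            h = block[2](h)
        return self.head(h)


class _DenseBlock(Module):
    """Each layer consumes the concatenation of all previous outputs."""

    def __init__(self, c_in, growth, n_layers, rng):
        self.layers = [ConvRelu(c_in + i * growth, growth, 3, rng)
                       for i in range(n_layers)]
        self.c_out = c_in + n_layers * growth

    def __call__(self, x):
        feats = x
        for layer in self.layers:
            feats = concat([feats, layer(feats)])
        return feats


class FCDenseNet(SegmentationModel):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        g, nl = config.growth_rate, config.block_layers
        self.stem = ConvRelu(3, config.base_width, 3, rng)
        c = config.base_width
        self.down_blocks, self.down_trans = [], []
        for _ in range(config.depth):
            block = _DenseBlock(c, g, nl, rng)
            self.down_blocks.append(block)
            c = block.c_out
            self.down_trans.append(ConvRelu(c, c, 1, rng))  # transition down conv
        self.bottleneck = _DenseBlock(c, g, nl, rng)
        c = self.bottleneck.c_out
        self.up_trans, self.up_blocks = [], []
        skip_channels = [b.c_out for b in self.down_blocks]
        for c_skip in reversed(skip_channels):
            self.up_trans.append(ConvRelu(c, c_skip, 3, rng))
            block = _DenseBlock(c_skip * 2, g, nl, rng)
            self.up_blocks.append(block)
            c = block.c_out
        self.head = Conv2d(c, config.n_classes, 1, rng)

    def forward(self, x):
        h = self.stem(x)
        skips = []
        for block, trans in zip(self.down_blocks, self.down_trans):
            h = block(h)
            skips.append(h)
            h = maxpool2d(trans(h))
        h = self.bottleneck(h)
        for trans, block, skip in zip(self.up_trans, self.up_blocks, reversed(skips)):
            h = trans(upsample_nearest(h, 2))
            h = block(concat([h, skip]))
        return self.head(h)


class DeepLabV3Plus(SegmentationModel):
    """Scaled-down DeepLabv3+: encoder, ASPP over ``atrous_rates``, decoder
    fusing a low-level feature map at 1/2 resolution.

    ``aspp_branches`` lists the parallel ASPP modules: one convolution per
    atrous rate plus the image-pooling branch.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        self.entry = ConvRelu(3, w, 3, rng)
        self.low_level = ConvRelu(w, w, 3, rng)          # at 1/2 resolution
        self.encoder = []
        c = w
        for level in range(1, config.depth):
            c_out = w * 2 ** level
            self.encoder.append(ConvRelu(c, c_out, 3, rng))
            c = c_out
        self.aspp_branches = []
        for rate in config.atrous_rates:
            kernel = 1 if rate == 1 else 3
            self.aspp_branches.append(ConvRelu(c, w, kernel, rng, dilation=rate))
        self.aspp_pool_conv = ConvRelu(c, w, 1, rng)
        self.aspp_branches.append(self.aspp_pool_conv)
        self.project = ConvRelu(w * len(self.aspp_branches), w, 1, rng)
        self.low_reduce = ConvRelu(w, w // 2 if w > 1 else 1, 1, rng)
        self.fuse = ConvRelu(w + (w // 2 if w > 1 else 1), w, 3, rng)
        self.head = Conv2d(w, config.n_classes, 1, rng)

    def forward(self, x):
        h = maxpool2d(self.entry(x))
        low = self.low_level(h)                   # skip at 1/2 resolution
        h = low
        for layer in self.encoder:
            h = maxpool2d(layer(h))
        hh, ww = h.data.shape[2], h.data.shape[3]
        branches = [branch(h) for branch in self.aspp_branches[:-1]]
        pooled = self.aspp_pool_conv(global_avg_pool(h))
        branches.append(broadcast_spatial(pooled, hh, ww))
        h = self.project(concat(branches))
        if self.config.depth > 1:
            h = upsample_nearest(h, 2 ** (self.config.depth - 1))
        h = self.fuse(concat([h, self.low_reduce(low)]))
        return self.head(upsample_nearest(h, 2))


_BUILDERS = {"unet": UNet, "fc_densenet": FCDenseNet, "deeplabv3plus": DeepLabV3Plus}


def build_model(config: ModelConfig) -> SegmentationModel:
    """Instantiate the architecture named in ``config`` with seeded init."""
    return _BUILDERS[config.architecture](config)
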