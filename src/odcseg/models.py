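"""Segmenter and domain-discriminator architectures.

The segmenter is a customized U-Net: four Double-Conv + max-pool encoder
stages (widths ``b, 2b, 4b, 8b`` for base width ``b``), a Double-Conv
bottom at width ``8b``, and four bilinear-upsample + Double-Conv decoder
stages mirroring the encoder with concatenated skip connections.  The
first decoder stage ("Up1") emits the encoding-space feature of width
``4b`` at 1/8 spatial resolution — for the reference width of 64 and a
256x256 input that is a 256x32x32 map.  A final 3x3 convolution and a
channel softmax produce the 3-class probability map over
{background, rim, cup}.

The domain discriminators are small fully-convolutional patch
classifiers: three 4x4 stride-2 convolutions, one 3x3 convolution (all
LeakyReLU) and a 3x3 output convolution to a single logit channel, an
exact 8x spatial downscale.  The channel progression for a 3-channel
(output-space) input is 3 -> 6 -> 12 -> 24 -> 1 and scales
proportionally with the input channel count for the encoding-space
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "SegmenterSpec",
    "DiscriminatorSpec",
    "ForwardOutputs",
    "UNetSegmenter",
    "PatchDiscriminator",
    "build_segmenter",
    "build_discriminator",
]


@dataclass(frozen=True)
class SegmenterSpec:
    """Architecture hyperparameters of the U-Net segmenter."""

    in_channels: int = 3
    n_classes: int = 3
    base_width: int = 64

    def __post_init__(self):
        if self.base_width % 4 != 0:
            raise ValueError("base_width must be divisible by 4")

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "n_classes": self.n_classes,
                "base_width": self.base_width}


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch-discriminator hyperparameters.

    ``in_channels`` is 3 for the output-space discriminator and
    ``base_width * 4`` for the encoding-space discriminator consuming the
    Up1 feature at native resolution.
    """

    in_channels: int = 3
    kernel_sizes: tuple[int, ...] = (4, 4, 4, 3, 3)
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    negative_slope: float = 0.2

    @property
    def widths(self) -> tuple[int, ...]:
        c = self.in_channels
        return (c, 2 * c, 4 * c, 8 * c, 1)

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels}


@dataclass
class ForwardOutputs:
    """Both feature spaces consumed by the domain discriminators."""

    encoding_feature: Tensor    # (N, 4b, H/8, W/8) Up1 feature
    probability_map: Tensor     # (N, n_classes, H, W) post-softmax


class _DoubleConv(nn.Module):
    """Conv3x3 -> BatchNorm -> ReLU, twice."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class UNetSegmenter(nn.Module):
    def __init__(self, spec: SegmenterSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        b = spec.base_width
        self.enc1 = _DoubleConv(spec.in_channels, b, rng)
        self.enc2 = _DoubleConv(b, 2 * b, rng)
        self.enc3 = _DoubleConv(2 * b, 4 * b, rng)
        self.enc4 = _DoubleConv(4 * b, 8 * b, rng)
        self.bottom = _DoubleConv(8 * b, 8 * b, rng)
        self.up1 = _DoubleConv(16 * b, 4 * b, rng)
        self.up2 = _DoubleConv(8 * b, 2 * b, rng)
        self.up3 = _DoubleConv(4 * b, b, rng)
        self.up4 = _DoubleConv(2 * b, b // 2, rng)
        self.head = nn.Conv2d(b // 2, spec.n_classes, 3, padding=1, rng=rng)

    def forward(self, x) -> ForwardOutputs:
        x = nn.as_tensor(x)
        _, _, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError(
                f"input spatial dimensions must be divisible by 16, got {h}x{w}")
        s1 = self.enc1(x)                          # b    @ H
        s2 = self.enc2(nn.max_pool2d(s1))          # 2b   @ H/2
        s3 = self.enc3(nn.max_pool2d(s2))          # 4b   @ H/4
        s4 = self.enc4(nn.max_pool2d(s3))          # 8b   @ H/8
        bt = self.bottom(nn.max_pool2d(s4))        # 8b   @ H/16
        u = nn.upsample_bilinear2d(bt, s4.shape[2:])
        enc_feature = self.up1(nn.concatenate([u, s4], axis=1))  # 4b @ H/8
        u = nn.upsample_bilinear2d(enc_feature, s3.shape[2:])
        u = self.up2(nn.concatenate([u, s3], axis=1))
        u = nn.upsample_bilinear2d(u, s2.shape[2:])
        u = self.up3(nn.concatenate([u, s2], axis=1))
        u = nn.upsample_bilinear2d(u, s1.shape[2:])
        u = self.up4(nn.concatenate([u, s1], axis=1))
        logits = self.head(u)
        probs = nn.softmax_channels(logits)
        return ForwardOutputs(encoding_feature=enc_feature,
                              probability_map=probs)

    # convenience inference path ---------------------------------------
    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Run one HxWx3 uint8 image through the net in eval mode."""
        was_training = self.training
        self.eval()
        x = np.asarray(image, dtype=np.float32) / 255.0
        x = x.transpose(2, 0, 1)[None]
        out = self.forward(Tensor(x))
        self.train(was_training)
        return out.probability_map.data[0]


class PatchDiscriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        widths = spec.widths
        chans = (spec.in_channels,) + widths
        layers: list[nn.Module] = []
        for i, (k, s) in enumerate(zip(spec.kernel_sizes, spec.strides)):
            layers.append(nn.Conv2d(chans[i], chans[i + 1], k, stride=s,
                                    padding=1, rng=rng))
            if i < len(spec.kernel_sizes) - 1:
                layers.append(nn.LeakyReLU(spec.negative_slope))
        self.body = nn.Sequential(*layers)

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        _, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValueError(
                f"discriminator expects {self.spec.in_channels} channels, got {c}")
        if h % 8 or w % 8:
            raise ValueError(
                f"input spatial dimensions must be divisible by 8, got {h}x{w}")
        return self.body(x)   # patch logits (N, 1, H/8, W/8)


def build_segmenter(spec: SegmenterSpec | None = None, *,
                    seed: int = 0) -> UNetSegmenter:
    spec = spec or SegmenterSpec()
    return UNetSegmenter(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec | None = None, *,
                        seed: int = 0) -> PatchDiscriminator:
    spec = spec or DiscriminatorSpec()
    return PatchDiscriminator(spec, np.random.default_rng(seed))
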