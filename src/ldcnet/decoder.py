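"""Decoder: FPN fusion of the encoder pyramid, criss-cross attention, head.

The four encoder levels (strides 4/8/16/32) pass through lateral 1x1
convolutions to a common width, are merged top-down (deeper level bilinearly
upsampled 2x and added), and each merged level is carried to stride 4 by a
chain of upsample blocks (0 for the stride-4 level, 3 for the stride-32
level) whose last block reduces to the per-level contribution width.
Channel concatenation of the four aligned maps gives the fused map — 64
channels at 64 x 64 for a 256 x 256 input.  Criss-cross attention refines the
fused map, and the segmentation head (3x3 depthwise-separable convolution,
1x1 convolution to the class count, 4x bilinear upsample) emits
full-resolution logits.  FPN and attention are independently toggleable so
the ablation's four configurations (baseline / +FPN / +CCAM / full) are all
reachable; the baseline merges the stride-4 level with a plain 1x1
convolution instead of the pyramid.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .ccam import CrissCrossAttention
from .config import ModelConfig
from .encoder import LDCNetEncoder
from .nn import tensor as T


class UpsampleBlock(nn.Module):
    """3x3 depthwise-separable conv, 1x1 conv, then 2x bilinear upsample."""

    def __init__(self, in_channels, out_channels, rng):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.body = nn.Sequential(
            nn.DepthwiseSeparable(in_channels, in_channels, 3, rng),
            nn.PointwiseConv(in_channels, out_channels, rng),
            nn.BatchNorm2d(out_channels),
            nn.ReLU(),
        )
        self.up = nn.BilinearUpsample(2, out_channels)

    def forward(self, x):
        return self.up(self.body(x))

    def count_macs(self, h, w):
        m, h, w = self.body.count_macs(h, w)
        mu, h, w = self.up.count_macs(h, w)
        return m + mu, h, w


class FPNFusion(nn.Module):
    """Top-down pyramid fusion to a single stride-4 map of 4 * level width."""

    def __init__(self, in_channels_per_level, config: ModelConfig, rng):
        super().__init__()
        if len(in_channels_per_level) != 4:
            raise ValueError("expected a four-level pyramid")
        fc = config.fpn_channels
        lc = config.level_channels
        self.fpn_channels = fc
        self.laterals = [
            nn.Sequential(nn.PointwiseConv(c, fc, rng), nn.BatchNorm2d(fc),
                          nn.ReLU())
            for c in in_channels_per_level
        ]
        self.up2 = nn.BilinearUpsample(2, fc)
        # level i (stride 4 * 2^i) needs i upsample blocks; the last one in
        # each chain reduces to the per-level contribution width
        self.chains = []
        for i in range(4):
            if i == 0:
                chain = [nn.Sequential(nn.PointwiseConv(fc, lc, rng),
                                       nn.BatchNorm2d(lc), nn.ReLU())]
            else:
                chain = [UpsampleBlock(fc, fc, rng) for _ in range(i - 1)]
                chain.append(UpsampleBlock(fc, lc, rng))
            self.chains.append(nn.Sequential(*chain))

    def forward(self, pyramid):
        if len(pyramid) != 4:
            raise ValueError("expected a four-level pyramid")
        laterals = [lat(x) for lat, x in zip(self.laterals, pyramid)]
        merged = [None] * 4
        merged[3] = laterals[3]
        for i in (2, 1, 0):
            merged[i] = T.add(laterals[i], self.up2(merged[i + 1]))
        aligned = [chain(m) for chain, m in zip(self.chains, merged)]
        return T.concat(aligned, axis=1)

    def count_macs(self, sizes):
        """``sizes``: list of (h, w) for the four levels, shallow to deep."""
        total = 0
        for lat, (h, w) in zip(self.laterals, sizes):
            total += lat.count_macs(h, w)[0]
        for i in (3, 2, 1):  # top-down 2x upsamples feeding levels 2..0
            total += self.up2.count_macs(*sizes[i])[0]
        for chain, (h, w) in zip(self.chains, sizes):
            total += chain.count_macs(h, w)[0]
        return total


class PlainMerge(nn.Module):
    """Ablation baseline: 1x1 conv of the stride-4 level to the fused width."""

    def __init__(self, in_channels, out_channels, rng):
        super().__init__()
        self.body = nn.Sequential(nn.PointwiseConv(in_channels, out_channels, rng),
                                  nn.BatchNorm2d(out_channels), nn.ReLU())

    def forward(self, pyramid):
        return self.body(pyramid[0])

    def count_macs(self, sizes):
        return self.body.count_macs(*sizes[0])[0]


class SegmentationHead(nn.Module):
    """3x3 depthwise-separable conv, 1x1 conv to classes, 4x bilinear up."""

    def __init__(self, in_channels, num_classes, rng):
        super().__init__()
        self.num_classes = num_classes
        self.body = nn.Sequential(
            nn.DepthwiseSeparable(in_channels, in_channels, 3, rng),
        )
        self.classifier = nn.PointwiseConv(in_channels, num_classes, rng,
                                           bias=True)
        self.up = nn.BilinearUpsample(4, num_classes)

    def forward(self, x, out_size=None):
        logits = self.classifier(self.body(x))
        if out_size is None:
            return self.up(logits)
        return T.bilinear_resize(logits, out_size, out_size)

    def count_macs(self, h, w):
        m, h, w = self.body.count_macs(h, w)
        mc, h, w = self.classifier.count_macs(h, w)
        mu, h, w = self.up.count_macs(h, w)
        return m + mc + mu, h, w


class LDCNetSegmenter(nn.Module):
    """End-to-end model: encoder -> (FPN | plain merge) -> (CCAM) -> head."""

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        config.validate()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = LDCNetEncoder(config, rng)
        fused = config.fused_channels
        if config.use_fpn:
            self.merge = FPNFusion(self.encoder.level_channels, config, rng)
        else:
            self.merge = PlainMerge(self.encoder.level_channels[0], fused, rng)
        if config.use_ccam:
            self.attention = CrissCrossAttention(fused, rng,
                                                 reduction=config.ccam_reduction)
        self.head = SegmentationHead(fused, config.num_classes, rng)

    def forward(self, image):
        """(N,3,H,W) image with H, W divisible by 32 -> (N,K,H,W) logits."""
        pyramid = self.encoder(image)
        fused = self.merge(pyramid)
        if self.config.use_ccam:
            fused = self.attention(fused)
        return self.head(fused)

    def predict(self, image):
        """Per-pixel argmax labels (N,H,W) in inference mode."""
        was_training = self.training
        self.eval()
        logits = self.forward(nn.as_tensor(image))
        if was_training:
            self.train()
        return np.argmax(logits.data, axis=1).astype(np.int64)

    def count_macs(self, input_size):
        if input_size % 32:
            raise ValueError("input size must be divisible by 32")
        total, _, _ = self.encoder.count_macs(input_size, input_size)
        sizes = [(input_size // s, input_size // s) for s in (4, 8, 16, 32)]
        total += self.merge.count_macs(sizes)
        if self.config.use_ccam:
            total += self.attention.count_macs(*sizes[0])[0]
        total += self.head.count_macs(*sizes[0])[0]
        return int(total)


def build_model(config: ModelConfig, seed=None) -> LDCNetSegmenter:
    """Construct a model; ``seed`` overrides the config's parameter-init seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return LDCNetSegmenter(config, rng)
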