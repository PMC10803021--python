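"""The LDCNet backbone: a four-stage densely connected encoder.

Each dense block is a two-branch bottleneck: a 7x7 and a 3x3 depthwise-
separable branch, both mapping the block input to ``growth`` channels; the
branch outputs are summed and concatenated with the input, so every block
adds ``growth`` channels (the DenseNet growth-rate pattern).  The 7x7 branch
gives a wide receptive field cheaply, the 3x3 branch keeps fine detail.

A two-convolution stride-2 stem brings the input to stride 4; stages are
separated by DenseNet-style transitions (1x1 compression then 2x2 average
pooling), so the four stage outputs form a pyramid at strides 4/8/16/32.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import tensor as T


class Bottleneck(nn.Module):
    """Dual-branch depthwise-separable bottleneck; output = concat(x, b7 + b3)."""

    def __init__(self, in_channels, growth, rng):
        super().__init__()
        self.in_channels = in_channels
        self.growth = growth
        self.out_channels = in_channels + growth
        self.branch7 = nn.DepthwiseSeparable(in_channels, growth, 7, rng)
        self.branch3 = nn.DepthwiseSeparable(in_channels, growth, 3, rng)

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        new = T.add(self.branch7(x), self.branch3(x))
        return T.concat([x, new], axis=1)

    def count_macs(self, h, w):
        m7, _, _ = self.branch7.count_macs(h, w)
        m3, _, _ = self.branch3.count_macs(h, w)
        return m7 + m3, h, w


class DenseStage(nn.Module):
    """``depth`` bottlenecks applied sequentially; adds depth * growth channels."""

    def __init__(self, in_channels, depth, growth, rng):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.in_channels = in_channels
        self.out_channels = in_channels + depth * growth
        self.blocks = [Bottleneck(in_channels + i * growth, growth, rng)
                       for i in range(depth)]

    def forward(self, x):
        for block in self.blocks:
            x = block(x)
        return x

    def count_macs(self, h, w):
        total = 0
        for block in self.blocks:
            m, h, w = block.count_macs(h, w)
            total += m
        return total, h, w


class Transition(nn.Module):
    """1x1 channel compression followed by 2x2 average pooling (stride 2)."""

    def __init__(self, in_channels, compression, rng):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = max(1, int(in_channels * compression))
        self.conv = nn.PointwiseConv(in_channels, self.out_channels, rng)
        self.norm = nn.BatchNorm2d(self.out_channels)
        self.act = nn.ReLU()
        self.pool = nn.AvgPool2()

    def forward(self, x):
        return self.pool(self.act(self.norm(self.conv(x))))

    def count_macs(self, h, w):
        m, h, w = self.conv.count_macs(h, w)
        return m, h // 2, w // 2


class LDCNetEncoder(nn.Module):
    """Backbone producing a four-level pyramid at strides 4, 8, 16, 32."""

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        config.validate()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        s = config.stem_channels
        # two stride-2 depthwise-separable convolutions: 3 -> s at stride 4
        self.stem = nn.Sequential(
            nn.DepthwiseSeparable(3, s, 3, rng, stride=2),
            nn.DepthwiseSeparable(s, s, 3, rng, stride=2),
        )
        self.stages = []
        self.transitions = []
        channels = s
        self.level_channels = []
        for i, (depth, growth) in enumerate(
                zip(config.stage_depths, config.growth_rates)):
            stage = DenseStage(channels, depth, growth, rng)
            self.stages.append(stage)
            self.level_channels.append(stage.out_channels)
            channels = stage.out_channels
            if i < 3:
                tr = Transition(channels, config.compression, rng)
                self.transitions.append(tr)
                channels = tr.out_channels

    def forward(self, x):
        """Map a (N,3,H,W) image (H, W divisible by 32) to four feature maps."""
        _, c, h, w = x.shape
        if c != 3:
            raise ValueError("encoder expects 3-channel input")
        if h % 32 or w % 32:
            raise ValueError("input spatial size must be divisible by 32")
        x = self.stem(x)
        levels = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            levels.append(x)
            if i < 3:
                x = self.transitions[i](x)
        return tuple(levels)

    def count_macs(self, h, w):
        total, h, w = self.stem.count_macs(h, w)
        for i, stage in enumerate(self.stages):
            m, h, w = stage.count_macs(h, w)
            total += m
            if i < 3:
                m, h, w = self.transitions[i].count_macs(h, w)
                total += m
        return total, h, w
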