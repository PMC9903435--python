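"""Residual networks (2-D and 3-D) emitting a single risk scalar.

The 2-D family follows the canonical topology: 7x7 stride-2 stem with a
3x3 stride-2 max pool, four stages with channel widths 64/128/256/512,
basic blocks at depths 18/34 and bottleneck blocks (expansion 4) at depth
50, global average pooling and a one-unit linear head.

The 3-D family uses 3x3x3 kernels throughout with batch normalization and
ReLU after each convolution, stride-2 convolutions for downsampling, and
adaptive average pooling before the linear head.  Its stem is the 3x3x3
stride-2 convolution plus a 2x2x2 stride-2 max pool (the /4 stem of the
residual family expressed with the 3x3x3 kernel).  Depths 10/18/34 use
basic blocks, so the pooled feature length is 512.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import (
    AdaptiveAvgPool,
    BatchNorm,
    Conv,
    Linear,
    MaxPool,
    Module,
    ReLU,
    Sequential,
)

WIDTHS = (64, 128, 256, 512)

#: blocks per stage for each supported depth
RESNET2D_LAYERS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3), 50: (3, 4, 6, 3)}
RESNET3D_LAYERS = {10: (1, 1, 1, 1), 18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}

MIN_SPATIAL_2D = 32
MIN_SPATIAL_3D = 16


class BasicBlock(Module):
    expansion = 1

    def __init__(self, nd, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = Conv(nd, in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm(out_ch)
        self.conv2 = Conv(nd, out_ch, out_ch, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm(out_ch)
        self.relu = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv(nd, in_ch, out_ch, 1, rng, stride=stride), BatchNorm(out_ch)
            )
        else:
            self.shortcut = None

    def forward(self, x):
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        identity = x if self.shortcut is None else self.shortcut(x)
        return self.relu(out + identity)


class Bottleneck(Module):
    expansion = 4

    def __init__(self, nd, in_ch, width, stride, rng):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = Conv(nd, in_ch, width, 1, rng)
        self.bn1 = BatchNorm(width)
        self.conv2 = Conv(nd, width, width, 3, rng, stride=stride, padding=1)
        self.bn2 = BatchNorm(width)
        self.conv3 = Conv(nd, width, out_ch, 1, rng)
        self.bn3 = BatchNorm(out_ch)
        self.relu = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv(nd, in_ch, out_ch, 1, rng, stride=stride), BatchNorm(out_ch)
            )
        else:
            self.shortcut = None

    def forward(self, x):
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        identity = x if self.shortcut is None else self.shortcut(x)
        return self.relu(out + identity)


class ResNet(Module):
    """Residual risk network; ``forward`` returns one scalar per subject.

    The pooled feature vector (before the linear head) is exposed through
    :meth:`features` for multimodal fusion.
    """

    def __init__(
        self,
        nd: int,
        block,
        layers_per_stage,
        rng: np.random.Generator,
        in_channels: int = 1,
    ):
        super().__init__()
        self.nd = nd
        self.min_spatial = MIN_SPATIAL_2D if nd == 2 else MIN_SPATIAL_3D
        if nd == 2:
            self.stem = Sequential(
                Conv(nd, in_channels, WIDTHS[0], 7, rng, stride=2, padding=3),
                BatchNorm(WIDTHS[0]),
                ReLU(),
                MaxPool(nd, 3, 2, padding=1),
            )
        else:
            self.stem = Sequential(
                Conv(nd, in_channels, WIDTHS[0], 3, rng, stride=2, padding=1),
                BatchNorm(WIDTHS[0]),
                ReLU(),
                MaxPool(nd, 2, 2),
            )
        stages = []
        in_ch = WIDTHS[0]
        for stage_idx, (width, n_blocks) in enumerate(zip(WIDTHS, layers_per_stage)):
            stride = 1 if stage_idx == 0 else 2
            blocks = []
            for b in range(n_blocks):
                blocks.append(block(nd, in_ch, width, stride if b == 0 else 1, rng))
                in_ch = width * block.expansion
            stages.append(Sequential(*blocks))
        self.stages = stages
        self.pool = AdaptiveAvgPool()
        self.feature_dim = WIDTHS[-1] * block.expansion
        self.fc = Linear(self.feature_dim, 1, rng)

    def _check_input(self, x: Tensor) -> None:
        if x.ndim == self.nd + 1:  # allow (N, *spatial): insert channel axis
            raise ValueError(
                f"expected (N, C, *spatial) input with {self.nd} spatial dims, "
                f"got shape {x.shape}"
            )
        spatial = x.shape[2:]
        if len(spatial) != self.nd or any(s < self.min_spatial for s in spatial):
            raise ValueError(
                f"input spatial shape {spatial} too small for the downsampling "
                f"chain; minimum is {(self.min_spatial,) * self.nd}"
            )

    def features(self, x: Tensor) -> Tensor:
        self._check_input(x)
        out = self.stem(x)
        for stage in self.stages:
            out = stage(out)
        return self.pool(out)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))


def resnet2d(depth: int, rng: np.random.Generator, in_channels: int = 1) -> ResNet:
    if depth not in RESNET2D_LAYERS:
        raise ValueError(
            f"unsupported 2-D ResNet depth {depth}; choose from {sorted(RESNET2D_LAYERS)}"
        )
    block = Bottleneck if depth == 50 else BasicBlock
    return ResNet(2, block, RESNET2D_LAYERS[depth], rng, in_channels)


def resnet3d(depth: int, rng: np.random.Generator, in_channels: int = 1) -> ResNet:
    if depth not in RESNET3D_LAYERS:
        raise ValueError(
            f"unsupported 3-D ResNet depth {depth}; choose from {sorted(RESNET3D_LAYERS)}"
        )
    return ResNet(3, BasicBlock, RESNET3D_LAYERS[depth], rng, in_channels)
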