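"""Residual CNN branch with parallel transformer fusion.

The CNN branch encodes the image from local to global through strided
residual blocks.  Under the parallel fusion strategy, each transformer
pyramid map is first upsampled x2 (bilinear) and then concatenated, channel
wise, with the running CNN feature right before the residual block operating
at that resolution; the block (stride 2) then produces the fused map F_i at
the same scale as the transformer map M_i.  With fusion disabled the branch
degenerates to a plain residual-CNN encoder on the image alone, which is the
CNN-only ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, bilinear_resize, concat
from .mit_encoder import PyramidFeatures
from .nn import BatchNorm2d, Conv2d, Module, ModuleList, default_rng

__all__ = [
    "ResidualBlockConfig", "FusedFeatures", "upsample2",
    "ResidualBlock", "FusionEncoder", "fusion_encode",
]


@dataclass(frozen=True)
class ResidualBlockConfig:
    in_channels: int
    out_channels: int
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")

    @property
    def needs_projection(self) -> bool:
        return self.in_channels != self.out_channels or self.stride != 1


@dataclass
class FusedFeatures:
    """CNN-branch maps F1..F4, spatially aligned with the pyramid M1..M4."""

    maps: list

    def __post_init__(self):
        if len(self.maps) != 4:
            raise ValueError("exactly 4 fused maps required")

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, i):
        return self.maps[i]


def upsample2(m) -> Tensor:
    """Double the spatial resolution by bilinear interpolation."""
    m = as_tensor(m)
    _, _, H, W = m.shape
    return bilinear_resize(m, 2 * H, 2 * W)


class ResidualBlock(Module):
    """Two conv-norm-activation units plus an (optionally projected) shortcut.

    Output = ReLU(BN(Conv3x3(ReLU(BN(Conv3x3_s(x))))) + shortcut(x)), with the
    stride applied in the first convolution; the shortcut is a strided 1x1
    conv + BN whenever channels or resolution change, identity otherwise.
    """

    def __init__(self, cfg: ResidualBlockConfig, rng=None):
        super().__init__()
        rng = default_rng(rng)
        self.cfg = cfg
        cin, cout, s = cfg.in_channels, cfg.out_channels, cfg.stride
        self.conv1 = Conv2d(cin, cout, 3, stride=s, padding=1, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, padding=1, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if cfg.needs_projection:
            self.short_conv = Conv2d(cin, cout, 1, stride=s, rng=rng, bias=False)
            self.short_bn = BatchNorm2d(cout)
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        if self.short_conv is not None:
            sc = self.short_bn(self.short_conv(x))
        else:
            sc = x
        return (h + sc).relu()


class FusionEncoder(Module):
    """Stem (7x7 stride-2 conv) + four stride-2 residual blocks with parallel
    transformer fusion before each block."""

    def __init__(self, mit_channels, rcnn_channels=(64, 128, 256, 512),
                 in_channels: int = 3, stem_kernel: int = 7,
                 fusion_enabled: bool = True, rng=None):
        super().__init__()
        rng = default_rng(rng)
        if len(rcnn_channels) != 4:
            raise ValueError("rcnn_channels must have 4 entries")
        self.fusion_enabled = fusion_enabled
        self.rcnn_channels = tuple(rcnn_channels)
        self.mit_channels = tuple(mit_channels)
        stem_ch = rcnn_channels[0]
        self.stem_conv = Conv2d(in_channels, stem_ch, stem_kernel, stride=2,
                                padding=stem_kernel // 2, rng=rng, bias=False)
        self.stem_bn = BatchNorm2d(stem_ch)
        blocks = []
        running = stem_ch
        for i in range(4):
            cin = running + (self.mit_channels[i] if fusion_enabled else 0)
            blocks.append(ResidualBlock(
                ResidualBlockConfig(cin, rcnn_channels[i], stride=2), rng=rng))
            running = rcnn_channels[i]
        self.blocks = ModuleList(blocks)

    def forward(self, img: Tensor, pyr: PyramidFeatures | None = None) -> FusedFeatures:
        img = as_tensor(img)
        if self.fusion_enabled and pyr is None:
            raise ValueError("fusion is enabled but no pyramid features given")
        x = self.stem_bn(self.stem_conv(img)).relu()       # 1/2 resolution
        maps = []
        for i, block in enumerate(self.blocks):
            if self.fusion_enabled:
                up = upsample2(pyr[i])                      # M_i doubled
                if up.shape[2:] != x.shape[2:]:
                    raise ValueError(
                        f"fusion misalignment at block {i + 1}: running "
                        f"feature {x.shape[2:]} vs upsampled pyramid "
                        f"{up.shape[2:]}")
                x = concat([x, up], axis=1)
            x = block(x)
            maps.append(x)
        return FusedFeatures(maps)


def fusion_encode(img, pyr: PyramidFeatures, mit_channels=None,
                  rcnn_channels=(64, 128, 256, 512), seed: int = 0) -> FusedFeatures:
    """Convenience: build a seeded fusion encoder and run one forward pass."""
    if mit_channels is None:
        mit_channels = tuple(m.shape[1] for m in pyr)
    enc = FusionEncoder(mit_channels, rcnn_channels,
                        rng=np.random.default_rng(seed))
    enc.eval()
    return enc(img, pyr)
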