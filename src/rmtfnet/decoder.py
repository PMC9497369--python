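"""Feature decoder: GFI-enriched skips, four decoder blocks, 7x7 head.

The global-feature-integration (GFI) module blends the transformer map X
(global attention) with the CNN map C (local detail) at the same scale:

    GFI(X, C) = Conv3x3([C' ; Conv3x3(X + C')])

where C' is C projected by a 1x1 convolution to X's channel count whenever
the two differ (the addition requires equal channels; the construction only
fixes the *output* channel count to match X).  The decoder starts from the
GFI-enriched bottleneck, and each decoder block doubles the resolution,
concatenates the same-scale skip, and applies two conv-BN-ReLU units.  After
four blocks (1/32 -> 1/2) a 7x7 convolution produces one-channel logits and
a final x2 bilinear upsample restores the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, bilinear_resize, concat
from .fusion_encoder import FusedFeatures, FusionEncoder, upsample2
from .mit_encoder import MiTConfig, MixTransformer, PyramidFeatures
from .nn import BatchNorm2d, Conv2d, Module, ModuleList, default_rng

__all__ = [
    "GFI", "DecoderBlock", "SegmentationHead",
    "RMTFNetConfig", "RMTFNet", "rmtf_forward",
]

VARIANTS = ("full", "backbone", "w_gfi", "w_hloss", "mit_only", "rcnn_only")


class GFI(Module):
    """Global feature integration skip module (see module docstring)."""

    def __init__(self, x_channels: int, c_channels: int, rng=None):
        super().__init__()
        rng = default_rng(rng)
        self.x_channels = x_channels
        if c_channels != x_channels:
            self.proj = Conv2d(c_channels, x_channels, 1, rng=rng)
        else:
            self.proj = None
        self.conv_inner = Conv2d(x_channels, x_channels, 3, padding=1, rng=rng)
        self.conv_outer = Conv2d(2 * x_channels, x_channels, 3, padding=1, rng=rng)

    def forward(self, X: Tensor, C: Tensor) -> Tensor:
        X, C = as_tensor(X), as_tensor(C)
        if X.shape[2:] != C.shape[2:]:
            raise ValueError(
                f"GFI spatial mismatch: X {X.shape[2:]} vs C {C.shape[2:]}")
        if self.proj is not None:
            C = self.proj(C)
        fused = self.conv_inner(X + C)
        return self.conv_outer(concat([C, fused], axis=1))


class DecoderBlock(Module):
    """x2 upsample, optional same-scale skip concat, then two conv-BN-ReLU."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 rng=None):
        super().__init__()
        rng = default_rng(rng)
        cin = in_channels + skip_channels
        self.conv1 = Conv2d(cin, out_channels, 3, padding=1, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1, rng=rng,
                            bias=False)
        self.bn2 = BatchNorm2d(out_channels)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        x = upsample2(as_tensor(x))
        if skip is not None:
            skip = as_tensor(skip)
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(
                    f"skip {skip.shape[2:]} does not match upsampled "
                    f"decoder state {x.shape[2:]}")
            x = concat([x, skip], axis=1)
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        return x


class SegmentationHead(Module):
    """7x7 convolution to one channel, then x2 bilinear to full resolution."""

    def __init__(self, in_channels: int, kernel: int = 7, rng=None):
        super().__init__()
        self.conv = Conv2d(in_channels, 1, kernel, padding=kernel // 2,
                           rng=default_rng(rng))

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        _, _, H, W = y.shape
        return bilinear_resize(y, 2 * H, 2 * W)


@dataclass(frozen=True)
class RMTFNetConfig:
    """Architecture switches.

    variant:
      full      — parallel-fusion encoder + GFI skips + (externally) the
                  hybrid loss;
      backbone  — GFI removed (skips are the fused maps F_i directly); the
                  training harness also drops the loss down to Dice-only;
      w_gfi     — backbone + GFI (ablation: GFI alone);
      w_hloss   — backbone + hybrid loss (ablation: loss alone; structurally
                  identical to backbone);
      mit_only  — decoder fed by the transformer maps M_i, no CNN branch;
      rcnn_only — CNN branch without fusion concatenation, no transformer
                  skips in the decoder.
    """

    variant: str = "full"
    mit_variant: str = "B"
    width_divisor: int = 1
    depths: tuple[int, ...] | None = None
    rcnn_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    decoder_channels: tuple[int, int, int, int] = (256, 128, 64, 32)
    head_kernel: int = 7
    threshold: float = 0.5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def use_gfi(self) -> bool:
        return self.variant in ("full", "w_gfi")

    @property
    def use_hybrid_loss(self) -> bool:
        return self.variant in ("full", "w_hloss")

    @classmethod
    def tiny(cls, variant: str = "full") -> "RMTFNetConfig":
        """Width-divided-by-8, depth-1 variant that trains on a CPU."""
        return cls(variant=variant, width_divisor=8, depths=(1, 1, 1, 1),
                   rcnn_channels=(8, 16, 32, 64),
                   decoder_channels=(32, 16, 8, 4))


class RMTFNet(Module):
    """Full encoder-decoder segmentation network (binary, one logit map)."""

    def __init__(self, cfg: RMTFNetConfig | None = None, in_channels: int = 3,
                 rng=None):
        super().__init__()
        self.cfg = cfg or RMTFNetConfig()
        rng = default_rng(rng)
        c = self.cfg

        mit_cfg = MiTConfig.build(c.mit_variant, width_divisor=c.width_divisor,
                                  depths=c.depths)
        self.mit_cfg = mit_cfg
        mit_dims = mit_cfg.embed_dims

        self.mit = None
        self.rcnn = None
        if c.variant != "rcnn_only":
            self.mit = MixTransformer(mit_cfg, in_channels, rng=rng)
        if c.variant != "mit_only":
            self.rcnn = FusionEncoder(
                mit_dims, c.rcnn_channels, in_channels,
                fusion_enabled=(c.variant != "rcnn_only"), rng=rng)

        # channel count of the skip at each scale, deepest last
        if c.variant == "mit_only":
            skip_ch = mit_dims
        elif c.use_gfi:
            skip_ch = mit_dims          # GFI output tracks channels(X)=C(M_i)
        else:
            skip_ch = c.rcnn_channels
        self.skip_channels = tuple(skip_ch)

        if c.use_gfi:
            self.gfis = ModuleList([
                GFI(mit_dims[i], c.rcnn_channels[i], rng=rng) for i in range(4)])
        else:
            self.gfis = None

        dch = c.decoder_channels
        blocks = []
        prev = skip_ch[3]               # bottleneck channels
        for i in range(4):
            skip = skip_ch[2 - i] if i < 3 else 0   # skips at 1/16, 1/8, 1/4
            blocks.append(DecoderBlock(prev, skip, dch[i], rng=rng))
            prev = dch[i]
        self.decoder = ModuleList(blocks)
        self.head = SegmentationHead(dch[3], c.head_kernel, rng=rng)

    # ------------------------------------------------------------ forward
    def encode(self, img: Tensor):
        """Return the list of four skip maps (shallow..deep)."""
        img = as_tensor(img)
        c = self.cfg
        if c.variant == "mit_only":
            return list(self.mit(img))
        if c.variant == "rcnn_only":
            return list(self.rcnn(img, None))
        pyr = self.mit(img)
        fused = self.rcnn(img, pyr)
        if c.use_gfi:
            return [g(m, f) for g, m, f in zip(self.gfis, pyr, fused)]
        return list(fused)

    def forward(self, img: Tensor) -> Tensor:
        img = as_tensor(img)
        B, C, H, W = img.shape
        if H % 32 or W % 32:
            raise ValueError(f"input size {H}x{W} must be divisible by 32")
        skips = self.encode(img)
        x = skips[3]                    # bottleneck at 1/32
        for i, block in enumerate(self.decoder):
            skip = skips[2 - i] if i < 3 else None
            x = block(x, skip)
        logits = self.head(x)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite logits")
        return logits

    def predict_proba(self, img) -> np.ndarray:
        self.eval()
        return self(img).sigmoid().data

    def predict_mask(self, img) -> np.ndarray:
        return (self.predict_proba(img) >= self.cfg.threshold).astype(np.uint8)


def rmtf_forward(img, cfg: RMTFNetConfig | None = None, seed: int = 0) -> Tensor:
    """Convenience: build a seeded network and return logits for one batch."""
    net = RMTFNet(cfg, rng=np.random.default_rng(seed))
    net.eval()
    return net(img)
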