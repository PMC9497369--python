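"""Hierarchical mix-transformer (MiT) encoder.

Produces four pyramid feature maps at 1/4, 1/8, 1/16 and 1/32 of the input
resolution with strictly increasing channel counts.  Each stage tokenizes its
input with an *overlapped* patch embedding (a strided convolution with kernel
larger than stride so neighbouring patches share pixels), then runs pre-norm
transformer blocks built from two pieces:

* efficient self-attention — the key/value sequence is shortened from N to
  N/R tokens before attention, realized as a strided convolution of stride
  sqrt(R) over the token grid (the same linear map on R-pixel blocks as a
  reshape-then-linear reduction), cutting the attention cost from O(N^2) to
  O(N^2 / R);
* Mix-FFN — an MLP with an internal depthwise 3x3 convolution on the token
  grid, which supplies positional information without explicit positional
  encodings.

Stage reduction ratios default to R = (64, 16, 4, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, concat, matmul, softmax
from .nn import (Conv2d, LayerNorm, Linear, Module, ModuleList, default_rng)

__all__ = [
    "StageConfig", "MiTConfig", "TokenMap", "PyramidFeatures",
    "OverlapPatchEmbed", "EfficientSelfAttention", "MixFFN",
    "TransformerBlock", "MixTransformer", "mit_forward",
]


# ---------------------------------------------------------------- configs
@dataclass(frozen=True)
class StageConfig:
    """Hyperparameters of one encoder stage.

    patch_kernel/stride/pad are the K, S, P of the overlapped patch
    embedding; ``reduction`` is the sequence-length reduction factor R of the
    efficient attention (must be a perfect square; the spatial reduction
    stride is sqrt(R)).
    """

    patch_kernel: int
    patch_stride: int
    patch_pad: int
    embed_dim: int
    depth: int
    heads: int
    reduction: int
    mlp_ratio: int = 4

    def __post_init__(self):
        if not (self.patch_kernel >= self.patch_stride >= 1):
            raise ValueError("require patch_kernel >= patch_stride >= 1")
        if self.patch_pad < 0:
            raise ValueError("patch_pad must be >= 0")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.reduction < 1:
            raise ValueError("reduction must be >= 1")
        r = int(round(self.reduction ** 0.5))
        if r * r != self.reduction:
            raise ValueError("reduction must be a perfect square")


_B_DIMS = (64, 128, 320, 512)
_B_DEPTHS = (3, 4, 6, 3)
_L_DEPTHS = (3, 6, 40, 3)
_HEADS = (1, 2, 5, 8)
_REDUCTIONS = (64, 16, 4, 1)
_PATCH = ((7, 4, 3), (3, 2, 1), (3, 2, 1), (3, 2, 1))


@dataclass(frozen=True)
class MiTConfig:
    stages: tuple[StageConfig, StageConfig, StageConfig, StageConfig]
    variant: str = "B"

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ValueError("exactly 4 stages required")
        dims = [s.embed_dim for s in self.stages]
        if not all(a < b for a, b in zip(dims, dims[1:])):
            raise ValueError("embed dims must strictly increase stage to stage")

    @property
    def embed_dims(self) -> tuple[int, ...]:
        return tuple(s.embed_dim for s in self.stages)

    @classmethod
    def build(cls, variant: str = "B", width_divisor: int = 1,
              depths: tuple[int, ...] | None = None) -> "MiTConfig":
        """Standard variants: "B" with depths (3,4,6,3), "L" with (3,6,40,3).

        ``width_divisor`` scales all embedding dims down (used for the tiny
        CPU-trainable variant); head counts are kept, so the divisor must
        leave each dim divisible by its head count.
        """
        if variant not in ("B", "L"):
            raise ValueError("variant must be 'B' or 'L'")
        if depths is None:
            depths = _B_DEPTHS if variant == "B" else _L_DEPTHS
        stages = tuple(
            StageConfig(patch_kernel=k, patch_stride=s, patch_pad=p,
                        embed_dim=d // width_divisor, depth=dep, heads=h,
                        reduction=r)
            for (k, s, p), d, dep, h, r in zip(_PATCH, _B_DIMS, depths,
                                               _HEADS, _REDUCTIONS))
        return cls(stages=stages, variant=variant)

    @classmethod
    def tiny(cls) -> "MiTConfig":
        """Dims divided by 8, one block per stage: trains in seconds on CPU."""
        return cls.build("B", width_divisor=8, depths=(1, 1, 1, 1))


# ------------------------------------------------------------------- types
@dataclass
class TokenMap:
    """A flattened token grid: ``tokens`` is (B, N, C) with N = H * W."""

    tokens: Tensor
    height: int
    width: int

    def __post_init__(self):
        self.tokens = as_tensor(self.tokens)
        if self.tokens.ndim != 3:
            raise ValueError("tokens must be (B, N, C)")
        if self.tokens.shape[1] != self.height * self.width:
            raise ValueError(
                f"N={self.tokens.shape[1]} != H*W={self.height * self.width}")

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[1]

    @property
    def channels(self) -> int:
        return self.tokens.shape[2]

    def to_map(self) -> Tensor:
        """(B, N, C) -> (B, C, H, W)."""
        B, N, C = self.tokens.shape
        return self.tokens.transpose(0, 2, 1).reshape(B, C, self.height, self.width)

    @classmethod
    def from_map(cls, x: Tensor) -> "TokenMap":
        B, C, H, W = x.shape
        return cls(x.reshape(B, C, H * W).transpose(0, 2, 1), H, W)


@dataclass
class PyramidFeatures:
    """The four MiT stage maps M1..M4 at 1/4, 1/8, 1/16, 1/32 resolution."""

    maps: list

    def __post_init__(self):
        if len(self.maps) != 4:
            raise ValueError("exactly 4 pyramid maps required")
        chans = [m.shape[1] for m in self.maps]
        if not all(a < b for a, b in zip(chans, chans[1:])):
            raise ValueError("channels must strictly increase across maps")
        for a, b in zip(self.maps, self.maps[1:]):
            if a.shape[2] != 2 * b.shape[2] or a.shape[3] != 2 * b.shape[3]:
                raise ValueError("each map must halve the previous resolution")

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, i):
        return self.maps[i]


# -------------------------------------------------------------- operations
class OverlapPatchEmbed(Module):
    """Strided K x K convolution (K > S: patches overlap) + token layer norm."""

    def __init__(self, in_channels: int, embed_dim: int,
                 kernel: int, stride: int, pad: int, rng=None):
        super().__init__()
        self.proj = Conv2d(in_channels, embed_dim, kernel,
                           stride=stride, padding=pad, rng=rng)
        self.norm = LayerNorm(embed_dim)
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: Tensor) -> TokenMap:
        x = as_tensor(x)
        B, C, H, W = x.shape
        if H + 2 * self.pad < self.kernel or W + 2 * self.pad < self.kernel:
            raise ValueError(
                f"input {H}x{W} too small for patch kernel {self.kernel} "
                f"with pad {self.pad}")
        y = self.proj(x)
        t = TokenMap.from_map(y)
        t.tokens = self.norm(t.tokens)
        return t


class EfficientSelfAttention(Module):
    """Sequence-reduced multi-head self-attention.

    Queries keep all N tokens; keys/values are shortened to N/R tokens by a
    strided sqrt(R) x sqrt(R) convolution over the token grid followed by a
    layer norm.  For R = 1 this reduces to ordinary full attention.  After a
    forward pass ``last_scores_shape`` records the (N, N/R) attention-matrix
    shape actually materialized, so the O(N^2 / R) cost contract can be
    asserted from outside.
    """

    def __init__(self, dim: int, heads: int, reduction: int, rng=None):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        rng = default_rng(rng)
        self.dim = dim
        self.heads = heads
        self.reduction = reduction
        self.q = Linear(dim, dim, rng=rng)
        self.kv = Linear(dim, 2 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.sr_stride = int(round(reduction ** 0.5))
        if self.sr_stride > 1:
            self.sr = Conv2d(dim, dim, self.sr_stride,
                             stride=self.sr_stride, rng=rng)
            self.sr_norm = LayerNorm(dim)
        self.last_scores_shape: tuple[int, int] | None = None

    def forward(self, t: TokenMap) -> TokenMap:
        B, N, C = t.tokens.shape
        if N % self.reduction:
            raise ValueError(f"token count {N} not divisible by R={self.reduction}")
        h = self.heads
        hd = C // h

        q = self.q(t.tokens)                                  # (B, N, C)
        if self.sr_stride > 1:
            s = self.sr_stride
            if t.height % s or t.width % s:
                raise ValueError(
                    f"grid {t.height}x{t.width} not divisible by "
                    f"reduction stride {s}")
            red = self.sr(t.to_map())                          # (B,C,H/s,W/s)
            red = TokenMap.from_map(red).tokens
            red = self.sr_norm(red)                            # (B, N/R, C)
        else:
            red = t.tokens
        kv = self.kv(red)                                      # (B, Nr, 2C)
        Nr = kv.shape[1]

        def split_heads(x: Tensor, n: int) -> Tensor:
            return x.reshape(B, n, h, hd).transpose(0, 2, 1, 3)

        qh = split_heads(q, N)
        kh = split_heads(kv[:, :, :C], Nr)
        vh = split_heads(kv[:, :, C:], Nr)

        scores = matmul(qh, kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        self.last_scores_shape = (scores.shape[2], scores.shape[3])
        attn = softmax(scores, axis=-1)                        # rows sum to 1
        self.last_attn = attn.data
        out = matmul(attn, vh)                                 # (B,h,N,hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, C)
        return TokenMap(self.proj(out), t.height, t.width)


class MixFFN(Module):
    """MLP with a depthwise 3x3 convolution on the token grid.

    ``forward`` applies the residual form x + MLP(GELU(Conv3x3(MLP(x))));
    ``core`` exposes the un-residual branch so the pre-norm transformer block
    can place the residual around the normalized input instead.
    """

    def __init__(self, dim: int, mlp_ratio: int = 4, rng=None):
        super().__init__()
        rng = default_rng(rng)
        hidden = dim * mlp_ratio
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.dwconv = Conv2d(hidden, hidden, 3, padding=1, groups=hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)

    def core(self, t: TokenMap) -> Tensor:
        x = self.fc1(t.tokens)
        g = TokenMap(x, t.height, t.width).to_map()
        g = self.dwconv(g)
        x = TokenMap.from_map(g).tokens
        x = x.gelu()
        return self.fc2(x)

    def forward(self, t: TokenMap) -> TokenMap:
        return TokenMap(t.tokens + self.core(t), t.height, t.width)


class TransformerBlock(Module):
    """Pre-norm block: x += Attn(LN(x)); x += MixFFN(LN(x))."""

    def __init__(self, dim: int, heads: int, reduction: int,
                 mlp_ratio: int = 4, rng=None):
        super().__init__()
        rng = default_rng(rng)
        self.norm1 = LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, reduction, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = MixFFN(dim, mlp_ratio, rng=rng)

    def forward(self, t: TokenMap) -> TokenMap:
        x = t.tokens
        n1 = TokenMap(self.norm1(x), t.height, t.width)
        x = x + self.attn(n1).tokens
        n2 = TokenMap(self.norm2(x), t.height, t.width)
        x = x + self.ffn.core(n2)
        return TokenMap(x, t.height, t.width)


class MixTransformer(Module):
    """Four-stage hierarchical encoder; returns the feature pyramid M1..M4."""

    def __init__(self, cfg: MiTConfig | None = None, in_channels: int = 3,
                 rng=None):
        super().__init__()
        self.cfg = cfg or MiTConfig.build("B")
        rng = default_rng(rng)
        embeds, stages, norms = [], [], []
        prev = in_channels
        for sc in self.cfg.stages:
            embeds.append(OverlapPatchEmbed(prev, sc.embed_dim, sc.patch_kernel,
                                            sc.patch_stride, sc.patch_pad, rng=rng))
            stages.append(ModuleList([
                TransformerBlock(sc.embed_dim, sc.heads, sc.reduction,
                                 sc.mlp_ratio, rng=rng)
                for _ in range(sc.depth)]))
            norms.append(LayerNorm(sc.embed_dim))
            prev = sc.embed_dim
        self.embeds = ModuleList(embeds)
        self.stages = ModuleList(stages)
        self.norms = ModuleList(norms)

    def forward(self, img: Tensor) -> PyramidFeatures:
        img = as_tensor(img)
        B, C, H, W = img.shape
        if H % 32 or W % 32:
            raise ValueError(f"input size {H}x{W} must be divisible by 32")
        x = img
        maps = []
        for embed, blocks, norm in zip(self.embeds, self.stages, self.norms):
            t = embed(x)
            for blk in blocks:
                t = blk(t)
            t.tokens = norm(t.tokens)
            x = t.to_map()
            maps.append(x)
        return PyramidFeatures(maps)


def mit_forward(img, cfg: MiTConfig | None = None, seed: int = 0) -> PyramidFeatures:
    """Convenience: build a seeded encoder and run one forward pass."""
    model = MixTransformer(cfg, rng=np.random.default_rng(seed))
    model.eval()
    return model(img)
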