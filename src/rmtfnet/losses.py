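"""Hybrid segmentation objective: L = alpha*Dice + beta*BCE + gamma*SSIM.

All three terms operate on sigmoid *probabilities* (not logits) against a
binary target, and every term is differentiable through the package's
autograd engine so the sum can train the network directly:

* Dice loss — 1 minus the soft Dice coefficient
  (2 sum(t_i e_i) + eps) / (sum t_i + sum e_i + eps); region-overlap driven
  and robust to foreground/background imbalance.
* Binary cross-entropy — the mean per-pixel log loss, with probabilities
  clamped away from {0, 1}.
* SSIM loss — 1 minus the mean windowed structural similarity
  ((2 mu1 mu2 + C1)(2 cov + C2)) / ((mu1^2 + mu2^2 + C1)(var1 + var2 + C2)),
  computed with a Gaussian window (default 11x11, sigma 1.5,
  C1 = (0.01 L)^2, C2 = (0.03 L)^2, dynamic range L = 1 for probability
  maps); it rewards local structural agreement, sharpening boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, conv2d

__all__ = [
    "LossWeights", "SSIMParams",
    "dice_coefficient", "dice_loss", "bce_loss",
    "ssim_map", "ssim_loss", "hybrid_loss",
]

DICE_EPS = 1e-6
BCE_CLIP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1.0   # Dice
    beta: float = 1.0    # BCE
    gamma: float = 1.0   # SSIM

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class SSIMParams:
    window_size: int = 11
    window_sigma: float = 1.5
    dynamic_range: float = 1.0

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.window_sigma <= 0:
            raise ValueError("window_sigma must be positive")

    @property
    def C1(self) -> float:
        return (0.01 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return (0.03 * self.dynamic_range) ** 2


def _check_shapes(e, t):
    if e.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {e.shape} vs target {t.shape}")


def dice_coefficient(e, t, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice overlap in [0, 1]; 1 at perfect prediction."""
    e, t = as_tensor(e), as_tensor(t)
    _check_shapes(e, t)
    inter = (e * t).sum()
    return (2.0 * inter + eps) / (t.sum() + e.sum() + eps)


def dice_loss(e, t, eps: float = DICE_EPS) -> Tensor:
    return 1.0 - dice_coefficient(e, t, eps)


def bce_loss(e, t, clip: float = BCE_CLIP) -> Tensor:
    """Mean binary cross-entropy over all pixels."""
    e, t = as_tensor(e), as_tensor(t)
    _check_shapes(e, t)
    ec = e.clip(clip, 1.0 - clip)
    ll = t * ec.log() + (1.0 - t) * (1.0 - ec).log()
    return -ll.mean()


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _to_nchw(x: Tensor) -> Tensor:
    if x.ndim == 2:
        return x.reshape(1, 1, *x.shape)
    if x.ndim == 3:
        return x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    if x.ndim == 4:
        return x
    raise ValueError(f"expected 2-4 dims, got {x.ndim}")


def ssim_map(I1, I2, params: SSIMParams | None = None) -> Tensor:
    """Per-window SSIM values over all fully-contained (valid) windows.

    Window statistics are Gaussian weighted; the output spatial size is
    (H - w + 1, W - w + 1) for window size w.
    """
    params = params or SSIMParams()
    I1, I2 = _to_nchw(as_tensor(I1)), _to_nchw(as_tensor(I2))
    _check_shapes(I1, I2)
    B, C, H, W = I1.shape
    w = params.window_size
    if w > H or w > W:
        raise ValueError(f"window {w} larger than image {H}x{W}")
    kern = _gaussian_window(w, params.window_sigma)
    weight = Tensor(np.broadcast_to(kern, (C, 1, w, w)).copy())

    def wmean(x: Tensor) -> Tensor:
        return conv2d(x, weight, stride=1, padding=0, groups=C)

    mu1, mu2 = wmean(I1), wmean(I2)
    var1 = wmean(I1 * I1) - mu1 * mu1
    var2 = wmean(I2 * I2) - mu2 * mu2
    cov = wmean(I1 * I2) - mu1 * mu2
    C1, C2 = params.C1, params.C2
    num = (2.0 * mu1 * mu2 + C1) * (2.0 * cov + C2)
    den = (mu1 * mu1 + mu2 * mu2 + C1) * (var1 + var2 + C2)
    return num / den


def ssim_loss(Is, Ig, params: SSIMParams | None = None) -> Tensor:
    """1 minus the mean windowed SSIM; 0 for identical images."""
    return 1.0 - ssim_map(Is, Ig, params).mean()


def hybrid_loss(e, t, weights: LossWeights | None = None,
                params: SSIMParams | None = None) -> Tensor:
    """Weighted Dice + BCE + SSIM sum; `e` must be probabilities in [0, 1]."""
    w = weights or LossWeights()
    total = as_tensor(0.0)
    if w.alpha:
        total = total + w.alpha * dice_loss(e, t)
    if w.beta:
        total = total + w.beta * bce_loss(e, t)
    if w.gamma:
        total = total + w.gamma * ssim_loss(e, t, params)
    return total
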