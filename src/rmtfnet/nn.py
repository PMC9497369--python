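"""Minimal neural-network layer library over :mod:`rmtfnet.autograd`.

Layers mirror the familiar framework surface (``Module``/``parameters``/
``train``/``eval``) so the model code reads like standard segmentation code.
Initialization is explicit and seeded: every layer takes a NumPy ``Generator``
so that a model built twice from the same seed is bitwise identical.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, matmul

__all__ = [
    "Parameter", "Module", "ModuleList", "Linear", "Conv2d",
    "LayerNorm", "BatchNorm2d", "Adam",
    "trunc_normal_", "default_rng",
]


def default_rng(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(0)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def trunc_normal_(shape, rng, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +-2 std by resampling."""
    rng = default_rng(rng)
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- flat float64 state dict, enough for single-file .npz checkpoints
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"__bnstats{i}.mean"] = m.running_mean.copy()
                out[f"__bnstats{i}.var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bnstats{i}.mean"]).copy()
                m.running_var = np.asarray(state[f"__bnstats{i}.var"]).copy()


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None, bias=True):
        super().__init__()
        rng = default_rng(rng)
        self.weight = Parameter(trunc_normal_((in_features, out_features), rng))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, groups: int = 1, rng=None, bias=True):
        super().__init__()
        rng = default_rng(rng)
        kh = kernel_size if isinstance(kernel_size, int) else kernel_size[0]
        kw = kernel_size if isinstance(kernel_size, int) else kernel_size[1]
        fan_out = out_channels * kh * kw // groups
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels // groups, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, groups=self.groups)


class LayerNorm(Module):
    """Normalization over the trailing (channel) axis of a token tensor."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size // C
            unbiased = var.data.reshape(C) * n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(C))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            xn = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            var = self.running_var.reshape(1, C, 1, 1)
            xn = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class Adam:
    """Adaptive-moment estimation with decoupled-from-nothing L2 weight decay
    folded into the gradient (classic Adam + weight_decay)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
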