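"""Reverse-mode automatic differentiation on NumPy arrays.

The segmentation network in this package is small enough to train on a CPU,
so instead of depending on a full deep-learning framework the package carries
its own tensor engine: a :class:`Tensor` wrapping an ``ndarray`` plus the
closed set of differentiable primitives the model needs (elementwise math,
reductions, matmul, 2-D convolution, bilinear resizing, shape surgery and the
usual activations).  Gradients are accumulated by a topological backward
sweep, exactly as in the mainstream frameworks.

Everything is computed in float64; the model is evaluated against
closed-form and brute-force oracles at tolerances (1e-5 .. 1e-6 relative)
that single precision would not comfortably clear.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

DTYPE = np.float64

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "matmul",
    "softmax",
    "conv2d",
    "bilinear_resize",
    "interp_matrix",
]


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        a, b = v
        return int(a), int(b)
    return int(v), int(v)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        assert np.isscalar(p), "only scalar exponents are supported"
        out = Tensor(self.data**p, _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    # ------------------------------------------------------------- unary math
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out.data)

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp; gradient passes through only inside the open interval."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                mask = (self.data > lo) & (self.data < hi)
                self._accumulate(g * mask)

        out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = _bw
        return out

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error-linear unit, 0.5 x (1 + erf(x/sqrt 2))."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / math.sqrt(2.0)))
        out = Tensor(x * cdf, _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accumulate(g * (cdf + x * pdf))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = [1 if i in axes else s for i, s in enumerate(self.data.shape)]
                gg = gg.reshape(shape)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a % self.data.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------- shape surgery
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = _bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    out.requires_grad = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = _bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.matmul(a.data, b.data), _prev=(a, b))
    out.requires_grad = a.requires_grad or b.requires_grad

    def _bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the shift is a constant w.r.t. the graph."""
    shift = x.data.max(axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# --------------------------------------------------------------------- conv2d
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout.

    Implemented as a sum over kernel offsets of strided views (cheap for the
    small kernels used here: 1x1, 3x3, 7x7), which keeps the backward pass a
    mirror-image scatter of the same views.
    """
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, Cin, H, W = x.data.shape
    Cout, cg, kh, kw = w.data.shape
    G = int(groups)
    og = Cout // G
    if Cin != cg * G or Cout % G:
        raise ValueError(
            f"conv2d channel mismatch: x has {Cin} channels, "
            f"weight implies {cg * G} (groups={G})")
    if H + 2 * ph < kh or W + 2 * pw < kw:
        raise ValueError(
            f"conv2d: padded input {H + 2 * ph}x{W + 2 * pw} smaller than "
            f"kernel {kh}x{kw}")
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hp, Wp = xp.shape[2:]
    xg = xp.reshape(B, G, cg, Hp, Wp)
    wg = w.data.reshape(G, og, cg, kh, kw)

    acc = np.zeros((B, G, og, Ho, Wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            xs = xg[:, :, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw]
            acc += np.einsum("bgchw,goc->bgohw", xs, wg[:, :, :, i, j],
                             optimize=True)
    y = acc.reshape(B, Cout, Ho, Wo)
    prev = (x, w) if b is None else (x, w, b)
    if b is not None:
        y = y + b.data.reshape(1, Cout, 1, 1)
    out = Tensor(y, _prev=prev)
    out.requires_grad = any(t.requires_grad for t in prev)

    def _bw(g):
        gg = g.reshape(B, G, og, Ho, Wo)
        if x.requires_grad:
            dxp = np.zeros((B, G, cg, Hp, Wp), dtype=DTYPE)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += \
                        np.einsum("bgohw,goc->bgchw", gg, wg[:, :, :, i, j],
                                  optimize=True)
            dx = dxp.reshape(B, Cin, Hp, Wp)[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(dx)
        if w.requires_grad:
            dw = np.zeros_like(wg)
            for i in range(kh):
                for j in range(kw):
                    xs = xg[:, :, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw]
                    dw[:, :, :, i, j] = np.einsum("bgohw,bgchw->goc", gg, xs,
                                                  optimize=True)
            w._accumulate(dw.reshape(Cout, cg, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out


# ----------------------------------------------------------- bilinear resize
def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-center convention)."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    for o in range(n_out):
        c = (o + 0.5) * n_in / n_out - 0.5
        c = min(max(c, 0.0), n_in - 1.0)
        lo = int(math.floor(c))
        hi = min(lo + 1, n_in - 1)
        f = c - lo
        M[o, lo] += 1.0 - f
        M[o, hi] += f
    return M


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor (exact linear map)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    A = interp_matrix(out_h, H)
    Bm = interp_matrix(out_w, W)
    y = np.matmul(np.matmul(A, x.data), Bm.T)
    out = Tensor(y, _prev=(x,))
    out.requires_grad = x.requires_grad

    def _bw(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(A.T, g), Bm))

    out._backward = _bw
    return out
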