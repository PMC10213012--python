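"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional generator/discriminator pairs on a
single CPU; this module provides the tensor type and the handful of
differentiable operations those networks need (elementwise arithmetic,
reductions, activations, padding, 2-D convolution, nearest-neighbour
up/down-sampling).  Everything is float64 so that finite-difference gradient
checks are meaningful to ~1e-7.

Gradients are accumulated by a topological-order sweep over the recorded
graph; ``Tensor.backward()`` seeds the sweep with ones (scalars are the
usual entry point).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "pad2d",
    "upsample2x",
    "avgpool2x",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array node in a dynamically recorded computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, iter(node._parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data**exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = [
                    1 if i in axes else s for i, s in enumerate(self.data.shape)
                ]
                g = g.reshape(shape)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ elementwise
    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accumulate(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bw(g):
            self._accumulate(g * factor)

        return Tensor(self.data * factor, _parents=(self,), _backward=bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accumulate(g * inside)

        return Tensor(
            np.clip(self.data, lo, hi), _parents=(self,), _backward=bw
        )

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bw)


def pad2d(x: Tensor, pad: int, mode: str = "zero") -> Tensor:
    """Pad the last two axes of an NCHW tensor by ``pad`` on each side."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    np_mode = {"zero": "constant", "reflect": "reflect"}[mode]
    out_data = np.pad(x.data, widths, mode=np_mode)

    def bw(g):
        core = g[..., pad:-pad, pad:-pad].copy()
        if mode == "reflect":
            h, w = x.data.shape[-2], x.data.shape[-1]
            # fold reflected borders back onto their source pixels
            core[..., 1 : pad + 1, :] += g[..., pad - 1 :: -1, pad:-pad]
            core[..., h - pad - 1 : h - 1, :] += g[..., : -pad - 1 : -1, pad:-pad]
            tmp = np.zeros_like(core)
            tmp[..., :, 1 : pad + 1] = g[..., pad:-pad, pad - 1 :: -1]
            tmp[..., :, w - pad - 1 : w - 1] = g[..., pad:-pad, : -pad - 1 : -1]
            # corners of the padded array reflect twice; handle via rows then cols
            corner = np.zeros_like(core)
            corner[..., 1 : pad + 1, 1 : pad + 1] = g[
                ..., pad - 1 :: -1, pad - 1 :: -1
            ]
            corner[..., 1 : pad + 1, w - pad - 1 : w - 1] = g[
                ..., pad - 1 :: -1, : -pad - 1 : -1
            ]
            corner[..., h - pad - 1 : h - 1, 1 : pad + 1] = g[
                ..., : -pad - 1 : -1, pad - 1 :: -1
            ]
            corner[..., h - pad - 1 : h - 1, w - pad - 1 : w - 1] = g[
                ..., : -pad - 1 : -1, : -pad - 1 : -1
            ]
            core += tmp + corner
        x._accumulate(core)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1) -> Tensor:
    """Valid 2-D cross-correlation of NCHW ``x`` with FCkk ``weight``.

    Padding is applied beforehand via :func:`pad2d`.  Implemented as one
    im2col GEMM (and its transpose pair in the backward pass), which is
    the fastest pure-numpy formulation for the small kernels used here;
    the column matrix is cached for the backward pass.
    """
    xd = x.data
    wd = weight.data
    n, c, h, w = xd.shape
    f, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
    if h < kh or w < kw:
        raise ValueError(
            f"input {h}x{w} smaller than kernel {kh}x{kw}: the image is too "
            "small for this network depth"
        )
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    cols2d = _im2col(xd, kh, kw, stride, ho, wo)
    out2d = wd.reshape(f, -1) @ cols2d
    out = out2d.reshape(f, n, ho, wo).transpose(1, 0, 2, 3)
    if bias is not None:
        out = out + bias.data.reshape(1, f, 1, 1)
    out = np.ascontiguousarray(out)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = g.transpose(1, 0, 2, 3).reshape(f, -1)
        weight._accumulate((g2 @ cols2d.T).reshape(wd.shape))
        # input gradient = full correlation of the (dilated) output grad
        # with the flipped, channel-transposed kernel — one more GEMM
        if stride == 1:
            gd = g
        else:
            gd = np.zeros((n, f, (ho - 1) * stride + 1, (wo - 1) * stride + 1))
            gd[:, :, ::stride, ::stride] = g
        pad_r_h = h + kh - 1 - (kh - 1) - gd.shape[2]
        pad_r_w = w + kw - 1 - (kw - 1) - gd.shape[3]
        gp = np.pad(gd, ((0, 0), (0, 0), (kh - 1, pad_r_h), (kw - 1, pad_r_w)))
        wflip = np.ascontiguousarray(
            wd[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        )
        cols_g = _im2col(gp, kh, kw, 1, h, w)
        gx = (wflip.reshape(c, -1) @ cols_g).reshape(c, n, h, w)
        x._accumulate(np.ascontiguousarray(gx.transpose(1, 0, 2, 3)))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor(out, _parents=parents, _backward=bw)


def _im2col(xd: np.ndarray, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """Column matrix (C*kh*kw, N*ho*wo) of sliding-window patches."""
    n, c = xd.shape[:2]
    view = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    return np.ascontiguousarray(
        view.transpose(1, 4, 5, 0, 2, 3)
    ).reshape(c * kh * kw, n * ho * wo)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the last two axes."""
    out_data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def bw(g):
        n, c, h2, w2 = g.shape
        x._accumulate(
            g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        )

    return Tensor(out_data, _parents=(x,), _backward=bw)


def avgpool2x(x: Tensor) -> Tensor:
    """2x average pooling of the last two axes (sizes must be even)."""
    n, c, h, w = x.data.shape
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bw(g):
        x._accumulate(g.repeat(2, axis=-2).repeat(2, axis=-1) * 0.25)

    return Tensor(out_data, _parents=(x,), _backward=bw)
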