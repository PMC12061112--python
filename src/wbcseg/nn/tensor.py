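"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation model only needs a handful of differentiable operations
(convolution, group normalization, ReLU, sigmoid, pooling, bilinear
upsampling, concatenation and elementwise arithmetic), so the engine is a
small tape-based Tensor rather than a general framework.  Every operation
records its parents and a closure that scatters the upstream gradient;
``Tensor.backward`` runs the tape in reverse topological order.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ----------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(data, (self, other), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise nonlinearities


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = _sigmoid_np(x.data)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def _sigmoid_np(u: np.ndarray) -> np.ndarray:
    # evaluate on the non-overflowing branch of exp for either sign
    dtype = u.dtype if u.dtype.kind == "f" else np.float64
    out = np.empty_like(u, dtype=dtype)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    e = np.exp(u[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def log(x: Tensor) -> Tensor:
    def backward(g):
        x._accumulate(g / x.data)
    return Tensor._make(np.log(x.data), (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(np.clip(x.data, lo, hi), (x,), backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        x._accumulate(np.full_like(x.data, float(g) / n))

    return Tensor._make(np.asarray(x.data.mean()), (x,), backward)


# ---------------------------------------------------------------------------
# structural ops


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, 'same'-padded 2-D convolution (cross-correlation).

    x: (N, C, H, W); w: (Cout, Cin, kh, kw) with odd kh, kw; b: (Cout,).
    Forward and both backward passes are im2col matrix products, so the
    whole cost lands in BLAS.
    """
    cols, xshape = _im2col(x.data, w.data.shape[2], w.data.shape[3])
    n, c, h, wd = xshape
    cout = w.data.shape[0]
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T  # (N*H*W, Cout)
    if b is not None:
        out = out + b.data
    data = out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            # gradient w.r.t. input = correlation of g with the flipped,
            # channel-transposed kernel (valid for stride-1 same padding)
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gcols, _ = _im2col(g, wflip.shape[2], wflip.shape[3])
            dx = gcols @ wflip.reshape(c, -1).T
            x._accumulate(dx.reshape(n, h, wd, c).transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(data, parents, backward)


def _im2col(x: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N*H*W, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * kh * kw)
    return cols, (n, c, h, w)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2 requires even spatial dimensions")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    return Tensor._make(data, (x,), backward)


def upsample_bilinear2(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling (half-pixel centers, edges clamped)."""
    n, c, h, w = x.data.shape
    mh = _interp_matrix(h, x.data.dtype)
    mw = _interp_matrix(w, x.data.dtype)
    data = np.einsum("ab,ncbd,ed->ncae", mh, x.data, mw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("ab,ncae,ed->ncbd", mh, g, mw, optimize=True))

    return Tensor._make(data, (x,), backward)


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def _interp_matrix(n: int, dtype=np.float64) -> np.ndarray:
    """(2n, n) linear-interpolation matrix for scale factor 2."""
    m = _INTERP_CACHE.get((n, np.dtype(dtype)))
    if m is None:
        src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n - 1)
        hi = np.clip(lo + 1, 0, n - 1)
        frac = np.clip(src - lo, 0.0, 1.0)
        m = np.zeros((2 * n, n))
        rows = np.arange(2 * n)
        np.add.at(m, (rows, lo), 1.0 - frac)
        np.add.at(m, (rows, hi), frac)
        m = m.astype(dtype)
        _INTERP_CACHE[(n, np.dtype(dtype))] = m
    return m


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, num_groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over (channels/group, H, W) per sample."""
    n, c, h, w = x.data.shape
    if c % num_groups:
        raise ValueError(f"channels {c} not divisible by groups {num_groups}")
    xg = x.data.reshape(n, num_groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    gam = gamma.data.reshape(1, c, 1, 1)
    data = xhat * gam + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = (g * gam).reshape(n, num_groups, -1)
            xh = xhat.reshape(n, num_groups, -1)
            m = gxh.shape[2]
            t1 = gxh - gxh.mean(axis=2, keepdims=True)
            t2 = xh * (gxh * xh).mean(axis=2, keepdims=True)
            x._accumulate(((t1 - t2) * inv).reshape(n, c, h, w))

    return Tensor._make(data, (x, gamma, beta), backward)
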