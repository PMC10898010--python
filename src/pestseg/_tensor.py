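"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains convolutional encoder–decoder networks on CPU, so the
engine implements exactly the operator set those models need: dilated 2-D
convolution with "same" padding, 2x2 max pooling, separable bilinear
resampling, global pooling, dense layers, elementwise nonlinearities and
the reductions used by the losses.  Tensors are NHWC (batch, height,
width, channel) and float64 throughout; every backward pass is verified
against central finite differences in the test suite.

This is deliberately a tape, not a framework: ops build closures that
push gradients to their parents, and :meth:`Tensor.backward` runs the
tape in reverse topological order.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "concat",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "conv2d",
    "dense",
    "maxpool2x2",
    "upsample_bilinear",
    "global_avg_pool",
    "global_max_pool",
    "interp_matrix",
]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parent."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, reciprocal(as_tensor(other)))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), reciprocal(self))

    def sum(self) -> "Tensor":
        return tsum(self)

    def mean(self) -> "Tensor":
        return mul(tsum(self), Tensor(1.0 / self.data.size))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def reciprocal(a: Tensor) -> Tensor:
    data = 1.0 / a.data

    def backward(g):
        a._accumulate(-g * data * data)

    return _make(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    data = np.empty_like(a.data)
    pos = a.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    data[~pos] = ex / (1.0 + ex)

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def tsum(a: Tensor) -> Tensor:
    data = np.asarray(a.data.sum())

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float64))

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(data, ts, backward)


# ---------------------------------------------------------------------------
# neural-net layers (NHWC)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, rate: int = 1) -> Tensor:
    """Dilated 2-D cross-correlation with "same" padding and stride 1.

    ``x``: (N, H, W, Cin); ``w``: (k, k, Cin, Cout); ``b``: (Cout,) or None.
    With dilation rate ``r`` the kernel taps sample the input at offsets
    ``r*i`` from the output position; the padding ``r*(k-1)/2`` keeps the
    output spatial size equal to the input's for odd ``k``.
    """
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    k = w.data.shape[0]
    if w.data.shape[1] != k or k % 2 == 0:
        raise ValueError(f"kernel must be square with odd edge, got {w.data.shape[:2]}")
    n, h, wd, cin = x.data.shape
    if w.data.shape[2] != cin:
        raise ValueError(
            f"kernel expects {w.data.shape[2]} input channels, image has {cin}"
        )
    cout = w.data.shape[3]
    pad = rate * (k // 2)
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # im2col: gather the k*k tap slices once, then a single BLAS matmul
    if k == 1:
        col = xp.reshape(-1, cin)
    else:
        col = np.empty((n, h, wd, k * k, cin))
        for i in range(k):
            for j in range(k):
                col[:, :, :, i * k + j, :] = xp[
                    :, i * rate : i * rate + h, j * rate : j * rate + wd, :
                ]
        col = col.reshape(-1, k * k * cin)
    wmat = w.data.reshape(k * k * cin, cout)
    out = col @ wmat
    if b is not None:
        out += b.data
    out = out.reshape(n, h, wd, cout)

    def backward(g):
        g2 = g.reshape(-1, cout)
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        w._accumulate((col.T @ g2).reshape(w.data.shape))
        dcol = (g2 @ wmat.T).reshape(n, h, wd, k * k, cin)
        if k == 1:
            x._accumulate(dcol.reshape(x.data.shape))
            return
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, i * rate : i * rate + h, j * rate : j * rate + wd, :] += dcol[
                    :, :, :, i * k + j, :
                ]
        if pad:
            x._accumulate(dxp[:, pad:-pad, pad:-pad, :])
        else:
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def dense(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Fully connected layer: (N, C) @ (C, M) + b."""
    data = x.data @ w.data
    if b is not None:
        data = data + b.data

    def backward(g):
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)
        if b is not None:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    windows = (
        x.data.reshape(n, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2, w2, c, 4)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = (
            dwin.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        x._accumulate(dx)

    return _make(out, (x,), backward)


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation matrix, half-pixel centers.

    Output sample ``o`` reads input coordinate ``(o + 0.5) * n_in/n_out - 0.5``
    with edge clamping (the convention of align_corners=False resizing).
    """
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0.0, n_in - 1.0)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = coords - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resampling of an NHWC tensor to ``out_hw``."""
    n, h, w, c = x.data.shape
    ho, wo = out_hw
    rmat = interp_matrix(h, ho)
    cmat = interp_matrix(w, wo)
    data = np.einsum("oh,nhwc->nowc", rmat, x.data, optimize=True)
    data = np.einsum("pw,nowc->nopc", cmat, data, optimize=True)

    def backward(g):
        # exact adjoint of the separable resampling
        d1 = np.einsum("pw,nopc->nowc", cmat, g, optimize=True)
        dx = np.einsum("oh,nowc->nhwc", rmat, d1, optimize=True)
        x._accumulate(dx)

    return _make(data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over spatial dims: (N, H, W, C) -> (N, 1, 1, C)."""
    n, h, w, c = x.data.shape
    data = x.data.mean(axis=(1, 2), keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    return _make(data, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """Max over spatial dims: (N, H, W, C) -> (N, 1, 1, C)."""
    n, h, w, c = x.data.shape
    flat = x.data.reshape(n, h * w, c)
    idx = flat.argmax(axis=1)
    data = np.take_along_axis(flat, idx[:, None, :], axis=1).reshape(n, 1, 1, c)

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, None, :], g.reshape(n, 1, c), axis=1)
        x._accumulate(dflat.reshape(x.data.shape))

    return _make(data, (x,), backward)
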