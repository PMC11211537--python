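"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the 3D multi-task model needs: broadcasted
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
reshapes, concatenation, stride-1 "same" 3D convolution, factor-2 pooling,
nearest-neighbour upsampling and trilinear resizing.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` over a
topologically sorted graph.  A module-level switch (:func:`no_grad`)
disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "grad_scale",
    "instance_norm",
    "concat",
    "conv3d",
    "pool3d",
    "upsample_nearest",
    "resize_trilinear",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_accum")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        arr = np.asarray(data, dtype=dtype)
        if arr.dtype.kind not in "fc":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, prev: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in prev if p.requires_grad or p._prev)
        if _grad_enabled and parents:
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                node._accum = grads  # type: ignore[attr-defined]
                node._backward(g)
                del node._accum  # type: ignore[attr-defined]

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        """Route a gradient contribution to ``parent`` during backward."""
        if not (parent.requires_grad or parent._prev):
            return
        acc = self._accum  # type: ignore[attr-defined]
        key = id(parent)
        if key in acc:
            acc[key] = acc[key] + g
        else:
            acc[key] = g

    # -- convenience ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            out._send(a, _unbroadcast(g, a.data.shape))
            out._send(b, _unbroadcast(g, b.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            out._send(a, -g)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            out._send(a, _unbroadcast(g * b.data, a.data.shape))
            out._send(b, _unbroadcast(g * a.data, b.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            out._send(a, _unbroadcast(g / b.data, a.data.shape))
            out._send(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g, a=self, e=exponent):
            out._send(a, g * e * a.data ** (e - 1))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            out._send(a, _unbroadcast(ga, a.data.shape))
            out._send(b, _unbroadcast(gb, b.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- elementwise ---------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self):
            out._send(a, g * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward(g, a=self):
            out._send(a, g / a.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self):
            out._send(a, g / (2.0 * out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self):
            out._send(a, g * mask)

        out = Tensor._make(self.data * mask, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self):
            out._send(a, g * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self):
            out._send(a, g * mask)

        out = Tensor._make(np.clip(self.data, lo, hi), (self,), backward)
        return out

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            out._send(a, np.broadcast_to(g, a.data.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            od, gg = out_data, g
            if ax is not None and not kd:
                od = np.expand_dims(od, ax)
                gg = np.expand_dims(gg, ax)
            mask = a.data == od
            counts = mask.sum(axis=ax, keepdims=True) if ax is not None else mask.sum()
            out._send(a, mask * (gg / counts))

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- shape ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g, a=self):
            out._send(a, g.reshape(orig))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g, a=self):
            out._send(a, g.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, key):
        def backward(g, a=self, k=key):
            full = np.zeros_like(a.data)
            np.add.at(full, k, g)
            out._send(a, full)

        out = Tensor._make(self.data[key], (self,), backward)
        return out

    # -- composite helpers --------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused per-case, per-channel normalisation over the spatial axes.

    x: (N, C, D, H, W); gamma/beta broadcastable (1, C, 1, 1, 1).
    """
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad or gamma._prev:
            out._send(gamma, (g * xhat).sum(axis=(0, *axes), keepdims=True))
        if beta.requires_grad or beta._prev:
            out._send(beta, g.sum(axis=(0, *axes), keepdims=True))
        if x.requires_grad or x._prev:
            gg = g * gamma.data
            gmean = gg.mean(axis=axes, keepdims=True)
            proj = (gg * xhat).mean(axis=axes, keepdims=True)
            out._send(x, inv * (gg - gmean - xhat * proj))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out


def grad_scale(x: Tensor, scale: float) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``scale``."""

    def backward(g):
        out._send(x, g * scale)

    out = Tensor._make(x.data, (x,), backward)
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            out._send(t, p)

    out = Tensor._make(np.concatenate(datas, axis=axis), tensors, backward)
    return out


# ---------------------------------------------------------------------
# 3D convolution / pooling / resizing
# ---------------------------------------------------------------------

def _pad_same(x: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    kd, kh, kw = kshape
    n, c, d, h, w = x.shape
    out = np.zeros((n, c, d + 2 * (kd // 2), h + 2 * (kh // 2), w + 2 * (kw // 2)),
                   dtype=x.dtype)
    out[:, :, kd // 2:kd // 2 + d, kh // 2:kh // 2 + h, kw // 2:kw // 2 + w] = x
    return out


def _offsets(kshape):
    kd, kh, kw = kshape
    return [(a, b, c) for a in range(kd) for b in range(kh) for c in range(kw)]


def _offset_views(xp: np.ndarray, kshape, shape):
    """Yield (flat kernel index, shifted flattened view) pairs."""
    n, c = xp.shape[:2]
    d, h, w = shape
    for i, (a, b, cc) in enumerate(_offsets(kshape)):
        yield i, xp[:, :, a:a + d, b:b + h, cc:cc + w].reshape(n, c, d * h * w)


def _conv3d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 "same" convolution by accumulation over kernel offsets."""
    n, _, d, hh, ww = x.shape
    cout = w.shape[0]
    kshape = tuple(w.shape[2:])
    wf = w.reshape(cout, w.shape[1], -1)
    if kshape == (1, 1, 1):
        out = np.matmul(wf[:, :, 0], x.reshape(n, x.shape[1], -1))
    else:
        xp = _pad_same(x, kshape)
        out = np.zeros((n, cout, d * hh * ww), dtype=x.dtype)
        for i, view in _offset_views(xp, kshape, (d, hh, ww)):
            out += np.matmul(wf[:, :, i], view)
    if b is not None:
        out = out + b[:, None]
    return out.reshape(n, cout, d, hh, ww)


def _conv3d_weight_grad(x: np.ndarray, g: np.ndarray, wshape) -> np.ndarray:
    """Gradient w.r.t. weights without materialising an im2col buffer."""
    n = x.shape[0]
    cout, cin = wshape[:2]
    kshape = tuple(wshape[2:])
    gflat = g.reshape(n, cout, -1)
    dw = np.empty((cout, cin, kshape[0] * kshape[1] * kshape[2]), dtype=x.dtype)
    if kshape == (1, 1, 1):
        dw[:, :, 0] = np.einsum("nop,ncp->oc", gflat, x.reshape(n, cin, -1))
    else:
        xp = _pad_same(x, kshape)
        for i, view in _offset_views(xp, kshape, x.shape[2:]):
            dw[:, :, i] = np.einsum("nop,ncp->oc", gflat, view)
    return dw.reshape(wshape)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero-padded "same" 3D convolution (odd kernels only).

    x: (N, Cin, D, H, W); w: (Cout, Cin, kd, kh, kw); b: (Cout,).
    """
    if any(k % 2 == 0 for k in w.data.shape[2:]):
        raise ValueError("conv3d supports odd kernel sizes only")
    out_data = _conv3d_raw(x.data, w.data, b.data)

    def backward(g):
        if w.requires_grad or w._prev:
            out._send(w, _conv3d_weight_grad(x.data, g, w.data.shape))
        if b.requires_grad or b._prev:
            out._send(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._prev:
            w_flip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            out._send(x, _conv3d_raw(g, np.ascontiguousarray(w_flip), None))

    out = Tensor._make(out_data, (x, w, b), backward)
    return out


def pool3d(x: Tensor, factors: tuple[int, int, int], mode: str = "max") -> Tensor:
    """Non-overlapping pooling by per-axis integer factors (each 1 or 2)."""
    fd, fh, fw = factors
    n, c, d, h, w = x.data.shape
    for name, size, f in (("slice", d, fd), ("row", h, fh), ("col", w, fw)):
        if size % f:
            raise ValueError(f"{name} axis of size {size} not divisible by pool factor {f}")
    xr = x.data.reshape(n, c, d // fd, fd, h // fh, fh, w // fw, fw)
    if mode == "avg":
        out_data = xr.mean(axis=(3, 5, 7))

        def backward(g):
            gg = g[:, :, :, None, :, None, :, None] / (fd * fh * fw)
            out._send(x, np.broadcast_to(gg, xr.shape).reshape(x.data.shape).copy())

    elif mode == "max":
        out_data = xr.max(axis=(3, 5, 7))

        def backward(g):
            ob = out_data[:, :, :, None, :, None, :, None]
            mask = xr == ob
            counts = mask.sum(axis=(3, 5, 7), keepdims=True)
            gg = g[:, :, :, None, :, None, :, None] / counts
            out._send(x, (mask * gg).reshape(x.data.shape))

    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    out = Tensor._make(out_data, (x,), backward)
    return out


def upsample_nearest(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    fd, fh, fw = factors
    out_data = x.data.repeat(fd, axis=2).repeat(fh, axis=3).repeat(fw, axis=4)

    def backward(g):
        n, c, d, h, w = x.data.shape
        gr = g.reshape(n, c, d, fd, h, fh, w, fw)
        out._send(x, gr.sum(axis=(3, 5, 7)))

    out = Tensor._make(out_data, (x,), backward)
    return out


def _linear_resize_plan(n_in: int, n_out: int):
    """Gather indices/weights for centre-aligned 1D linear interpolation."""
    if n_in == n_out:
        return None
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0, n_in - 1)
    i0 = np.floor(coords).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (coords - i0).astype(np.float64)
    return i0, i1, w1


def _apply_axis_interp(arr: np.ndarray, plan, axis: int) -> np.ndarray:
    if plan is None:
        return arr
    i0, i1, w1 = plan
    a0 = np.take(arr, i0, axis=axis)
    a1 = np.take(arr, i1, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = -1
    w1 = w1.reshape(shape)
    return a0 * (1.0 - w1) + a1 * w1


def _adjoint_axis_interp(g: np.ndarray, plan, axis: int, n_in: int) -> np.ndarray:
    if plan is None:
        return g
    i0, i1, w1 = plan
    shape = list(g.shape)
    shape[axis] = n_in
    outg = np.zeros(shape, dtype=g.dtype)
    wshape = [1] * g.ndim
    wshape[axis] = -1
    w1r = w1.reshape(wshape)
    gm = np.moveaxis(outg, axis, 0)
    np.add.at(gm, i0, np.moveaxis(g * (1.0 - w1r), axis, 0))
    np.add.at(gm, i1, np.moveaxis(g * w1r, axis, 0))
    return outg


def resize_trilinear(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    """Resize spatial dims of (N, C, D, H, W) to ``target`` by trilinear interpolation."""
    n, c, d, h, w = x.data.shape
    plans = [
        _linear_resize_plan(d, target[0]),
        _linear_resize_plan(h, target[1]),
        _linear_resize_plan(w, target[2]),
    ]
    out_data = x.data
    for axis, plan in enumerate(plans):
        out_data = _apply_axis_interp(out_data, plan, axis + 2)
    out_data = np.ascontiguousarray(out_data, dtype=x.data.dtype)

    def backward(g):
        gg = g
        sizes = (d, h, w)
        for axis in (2, 1, 0):
            gg = _adjoint_axis_interp(gg, plans[axis], axis + 2, sizes[axis])
        out._send(x, gg)

    out = Tensor._make(out_data, (x,), backward)
    return out
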