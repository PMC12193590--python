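"""Reverse-mode automatic differentiation over numpy arrays.

This is a compact tape-based autodiff engine providing exactly the operator
set the segmentation network needs: elementwise arithmetic, activations,
reductions, 2-D convolution (stride 1, 'same' zero padding), 2x2/stride-2
transposed convolution and max pooling, matrix products, reshaping and
channel concatenation.  All computation is float32; convolutions are lowered
to BLAS matrix products via im2col/col2im so a CPU run stays fast.

Gradients are accumulated by a topological backward sweep from the output
node; every primitive stores a closure that maps the output gradient to the
parent gradients (broadcasting is undone by summation).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "pow_", "log", "exp",
    "sigmoid", "relu", "clip",
    "sum_", "mean", "max_", "matmul", "reshape", "concat",
    "conv2d", "conv_transpose2x2", "maxpool2x2",
]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this node; ``grad`` defaults to ones."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node: Tensor):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go; leaves keep their grads
            if node._parents:
                node._backward = None
                node._parents = ()
                if not node.requires_grad:
                    node.grad = None

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return max_(self, axis, keepdims)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- helpers -------------------------------------------------------------

def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = np.asarray(g, dtype=np.float32)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))
    return _node(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape))
    return _node(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))
    return _node(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))
    return _node(a.data / b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, -g)
    return _node(-a.data, (a,), bw)


def pow_(a: Tensor, p: float) -> Tensor:
    out = a.data ** p

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1))
    return _node(out, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g / a.data)
    return _node(np.log(a.data), (a,), bw)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)

    def bw(g):
        _accum(a, g * out)
    return _node(out, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out[~pos] = ez / (1.0 + ez)

    def bw(g):
        _accum(a, g * out * (1.0 - out))
    return _node(out, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)
    return _node(a.data * mask, (a,), bw)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.data > lo) & (a.data < hi)

    def bw(g):
        _accum(a, g * mask)
    return _node(np.clip(a.data, lo, hi), (a,), bw)


# -- reductions / shaping ------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape))
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(gg, a.shape))
    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis, keepdims), Tensor(np.float32(1.0 / n)))


def max_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    """Max reduction over a single axis (or all elements)."""
    if axis is None:
        flat = a.data.reshape(-1)
        idx = int(flat.argmax())

        def bw(g):
            gg = np.zeros_like(a.data).reshape(-1)
            gg[idx] = float(g)
            _accum(a, gg.reshape(a.shape))
        return _node(flat[idx], (a,), bw)

    idx = a.data.argmax(axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

    def bw(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        full = np.zeros_like(a.data)
        np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
        _accum(a, full)
    return _node(out if keepdims else np.squeeze(out, axis), (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)
    return _node(a.data @ b.data, (a, b), bw)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.shape

    def bw(g):
        _accum(a, g.reshape(orig))
    return _node(a.data.reshape(shape), (a,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# -- convolution ---------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) for stride-1 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    cols = cols.reshape(n, c, k, k, h, w)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad:-pad, pad:-pad]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 zero-padded convolution preserving H and W.

    ``weight`` has shape (C_out, C_in, k, k) with k odd; ``bias`` (C_out,).
    """
    co, ci, k, k2 = weight.shape
    if k != k2 or k % 2 == 0:
        raise ValueError(f"conv2d requires a square odd kernel, got {k}x{k2}")
    n, c, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    pad = (k - 1) // 2
    cols = _im2col(x.data, k, pad)                       # (N, CKK, HW)
    wmat = weight.data.reshape(co, ci * k * k)
    out = np.matmul(wmat, cols).reshape(n, co, h, w)
    if bias is not None:
        out += bias.data.reshape(1, co, 1, 1)

    def bw(g):
        gmat = g.reshape(n, co, h * w)
        dw = np.einsum("nol,nkl->ok", gmat, cols, optimize=True)
        _accum(weight, dw.reshape(weight.shape))
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(wmat.T, gmat)                  # (N, CKK, HW)
        _accum(x, _col2im(dcols, (n, c, h, w), k, pad))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(out, parents, bw)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2 kernel, stride-2 transposed convolution (doubles H and W).

    ``weight`` has shape (C_in, C_out, 2, 2).  With kernel == stride the
    output positions partition exactly, so each tap is a plain tensordot.
    """
    ci, co, k, k2 = weight.shape
    if (k, k2) != (2, 2):
        raise ValueError("conv_transpose2x2 expects a 2x2 kernel")
    n, c, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv_transpose channel mismatch: input {c}, weight {ci}")
    out = np.empty((n, co, 2 * h, 2 * w), dtype=np.float32)
    for i in range(2):
        for j in range(2):
            out[:, :, i::2, j::2] = np.tensordot(
                x.data, weight.data[:, :, i, j], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    if bias is not None:
        out += bias.data.reshape(1, co, 1, 1)

    def bw(g):
        dx = np.zeros_like(x.data)
        dw = np.empty_like(weight.data)
        for i in range(2):
            for j in range(2):
                gij = g[:, :, i::2, j::2]
                dx += np.tensordot(gij, weight.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
                dw[:, :, i, j] = np.einsum("nchw,nohw->co", x.data, gij, optimize=True)
        _accum(x, dx)
        _accum(weight, dw)
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(out, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (H and W must be even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    hh, ww = h // 2, w // 2
    win = x.data.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        full = np.zeros((n, c, hh, ww, 4), dtype=np.float32)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        _accum(x, full.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))

    return _node(out, (x,), bw)
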