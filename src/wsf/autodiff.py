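"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the segmentation network needs:
broadcasted arithmetic, batched matmul, shape manipulation, reductions,
pointwise nonlinearities, grouped 2-D convolution (im2col/col2im) and
bilinear/nearest resampling. Gradients accumulate into ``Tensor.grad``
after calling :meth:`Tensor.backward` on a scalar.

All computation is float32 by default; the graph is dynamic and built
eagerly, torch-style, but there is no graph retention: each backward
pass consumes the tape built by the forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "bilinear_resize", "upsample_nearest"]

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self.name = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = self.data ** exponent

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out, (self, other), bw)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        out = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out, (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                shape = [1 if i in axes else s for i, s in enumerate(self.shape)]
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise -----------------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out)

        return Tensor._make(out, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out * out))

        return Tensor._make(out, (self,), bw)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        c = np.sqrt(2.0 / np.pi).astype(DTYPE)
        inner = self * (self * self * 0.044715 + 1.0) * c
        return self * (inner.tanh() + 1.0) * 0.5

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out, tuple(tensors), bw)


# -- convolution -------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C, kh, kw, Ho, Wo) view-backed column array."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    _, _, _, _, ho, wo = cols.shape
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation; ``w`` has shape (Cout, Cin/groups, kh, kw)."""
    n, cin, h, win = x.shape
    cout, cin_g, kh, kw = w.shape
    if cin != cin_g * groups:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_g * groups}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    # (N, G, Cin/g * kh * kw, Ho*Wo)
    cols_g = cols.reshape(n, groups, cin_g * kh * kw, ho * wo)
    w_g = w.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.einsum("gok,ngkl->ngol", w_g, cols_g, optimize=True)
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g4 = g.reshape(n, groups, cout // groups, ho * wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", g4, cols_g, optimize=True)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.einsum("gok,ngol->ngkl", w_g, g4, optimize=True)
            gcols = gcols.reshape(n, cin, kh, kw, ho, wo)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride, padding))

    return Tensor._make(out, parents, bw)


# -- resampling --------------------------------------------------------

def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Resize (N, C, H, W) to (N, C, out_h, out_w), align_corners=False."""
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    mh = _linear_matrix(out_h, h)
    mw = _linear_matrix(out_w, w)
    out = np.einsum("oh,nchw,pw->ncop", mh, x.data, mw, optimize=True)

    def bw(g):
        if x.requires_grad:
            x._accum(np.einsum("oh,ncop,pw->nchw", mh, g, mw, optimize=True))

    return Tensor._make(out, (x,), bw)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Integer-factor nearest-neighbour upsampling of (N, C, H, W)."""
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def bw(g):
        if x.requires_grad:
            gr = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accum(gr)

    return Tensor._make(out, (x,), bw)
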