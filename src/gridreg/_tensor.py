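"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape-based engine sized for this package: dense tensors, static
graphs rebuilt per step, and the handful of operations the registration
network needs (elementwise arithmetic, matmul, reductions, shape ops,
strided 3D convolution, separable linear resampling, and trilinear warping).
Gradients are accumulated by topological traversal from the loss; every
operation's backward rule is unit-tested against central finite differences.
"""

from __future__ import annotations

import ctypes

import numpy as np

# Recycle large temporaries from the heap instead of mmap-ing each one:
# elementwise passes over attention-sized arrays are otherwise dominated by
# page-fault cost rather than arithmetic. Best-effort; harmless if absent.
try:                                       # pragma: no branch
    _libc = ctypes.CDLL("libc.so.6")
    _libc.mallopt(-3, 32 * 1024 * 1024)    # M_MMAP_THRESHOLD
    _libc.mallopt(-1, 64 * 1024 * 1024)    # M_TRIM_THRESHOLD
except (OSError, AttributeError):          # pragma: no cover
    pass

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "conv3d",
           "axis_linear3", "warp_trilinear", "scaled_dot_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autodiff core ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = np.asarray(grad, dtype=self.data.dtype)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.data.dtype)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        # close over the value array, not the output tensor (no ref cycle)
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def softplus(self):
        # log(1 + e^x); derivative is the logistic, computed overflow-free
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))
        sig = np.exp(self.data - out.data)      # e^x / (1 + e^x)
        out._backward = lambda g: self._accum(g * sig)
        return out

    def clip_min(self, lo: float):
        mask = self.data > lo
        out = Tensor(np.maximum(self.data, lo), parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.ndim for a in ax)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw
        return out

    def softmax(self, axis=-1):
        """Row-stochastic softmax (fused, max-shifted for stability)."""
        x = self.data
        y = np.exp(x - x.max(axis=axis, keepdims=True))
        y /= y.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * y)
        out._backward = bw
        return out


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if dtype is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=dtype))
    return Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    out._backward = bw
    return out


def scaled_dot_softmax(q: Tensor, k: Tensor, scale: float,
                       mask_bias: np.ndarray | None = None) -> Tensor:
    """Row-stochastic attention matrix softmax(scale * q @ k^T + bias).

    q: (..., G, d), k: (..., Np, d) -> (..., G, Np). Fused so the raw logits
    are computed in place and only the normalized attention matrix is kept
    for the backward pass (the logits of an attention layer are its largest
    intermediate). ``mask_bias`` is an additive array broadcast onto the
    logits (use large negatives to mask tokens out).
    """
    q, k = as_tensor(q), as_tensor(k)
    logits = np.matmul(q.data, np.swapaxes(k.data, -1, -2))
    logits *= scale
    if mask_bias is not None:
        logits += mask_bias
    logits -= logits.max(axis=-1, keepdims=True)
    np.exp(logits, out=logits)
    logits /= logits.sum(axis=-1, keepdims=True)
    y = logits
    out = Tensor(y, parents=(q, k))

    def bw(g):
        gl = g * y
        dot = gl.sum(axis=-1, keepdims=True)
        gl -= dot * y
        gl *= scale
        if q.requires_grad:
            q._accum(_unbroadcast(np.matmul(gl, k.data), q.shape))
        if k.requires_grad:
            k._accum(_unbroadcast(np.matmul(np.swapaxes(gl, -1, -2), q.data),
                                  k.shape))
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Structured linear operators with hand-written adjoints
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """3D convolution, x: (B, Cin, X, Y, Z), w: (Cout, Cin, k, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    k = w.shape[-1]
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                    axis=(2, 3, 4))
    view = view[:, :, ::s, ::s, ::s]          # (B,Cin,Xo,Yo,Zo,k,k,k)
    out_data = np.einsum("bcxyzijk,ocijk->boxyz", view, w.data,
                         optimize=True)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]
    out = Tensor(out_data, parents=parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.einsum("bcxyzijk,boxyz->ocijk", view, g, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            Xo, Yo, Zo = g.shape[2:]
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        contrib = np.einsum("boxyz,oc->bcxyz", g,
                                            w.data[:, :, i, j, l],
                                            optimize=True)
                        gxp[:, :, i:i + s * Xo:s, j:j + s * Yo:s,
                            l:l + s * Zo:s] += contrib
            if p:
                gxp = gxp[:, :, p:-p, p:-p, p:-p]
            x._accum(gxp)
    out._backward = bw
    return out


def axis_linear3(x: Tensor, wx: np.ndarray, wy: np.ndarray,
                 wz: np.ndarray) -> Tensor:
    """Separable linear map over the last three axes.

    x: (..., X, Y, Z) -> (..., A, B, C) with out = Σ wx[a,i] wy[b,j] wz[c,k] x[...,i,j,k].
    The weight matrices are constants (resampling stencils); the op is linear
    in x, so the adjoint just applies the transposed stencils.
    """
    x = as_tensor(x)
    wx = np.asarray(wx, dtype=x.data.dtype)
    wy = np.asarray(wy, dtype=x.data.dtype)
    wz = np.asarray(wz, dtype=x.data.dtype)
    out_data = np.einsum("ai,bj,ck,...ijk->...abc", wx, wy, wz, x.data,
                         optimize=True)
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        gx = np.einsum("ai,bj,ck,...abc->...ijk", wx, wy, wz, g,
                       optimize=True)
        x._accum(gx)
    out._backward = bw
    return out


def warp_trilinear(moving: np.ndarray, ddf: Tensor) -> Tensor:
    """Backward-warp `moving` (X,Y,Z) by a gather displacement field.

    ddf: Tensor (3, X, Y, Z) in voxel units; output(x) = moving(x + ddf(x))
    with trilinear sampling and border clamping. Differentiable w.r.t. ddf
    (the image itself is a constant).
    """
    ddf = as_tensor(ddf)
    shape = moving.shape
    grids = np.meshgrid(*[np.arange(n, dtype=ddf.data.dtype) for n in shape],
                        indexing="ij")
    pos = np.stack(grids) + ddf.data               # (3, X, Y, Z)
    lim = np.array(shape, dtype=ddf.data.dtype) - 1
    pos_c = np.clip(pos, 0.0, lim[:, None, None, None])
    f = np.floor(pos_c)
    f = np.minimum(f, (lim - 1).clip(min=0)[:, None, None, None])
    t = pos_c - f                                   # fractional part in [0,1]
    f = f.astype(np.intp)

    def gather(dx, dy, dz):
        ix = np.clip(f[0] + dx, 0, shape[0] - 1)
        iy = np.clip(f[1] + dy, 0, shape[1] - 1)
        iz = np.clip(f[2] + dz, 0, shape[2] - 1)
        return moving[ix, iy, iz]

    c = {(dx, dy, dz): gather(dx, dy, dz)
         for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)}
    tx, ty, tz = t
    # interpolate along z, then y, then x
    c00 = c[0, 0, 0] * (1 - tz) + c[0, 0, 1] * tz
    c01 = c[0, 1, 0] * (1 - tz) + c[0, 1, 1] * tz
    c10 = c[1, 0, 0] * (1 - tz) + c[1, 0, 1] * tz
    c11 = c[1, 1, 0] * (1 - tz) + c[1, 1, 1] * tz
    c0 = c00 * (1 - ty) + c01 * ty
    c1 = c10 * (1 - ty) + c11 * ty
    out_data = c0 * (1 - tx) + c1 * tx
    out = Tensor(out_data, parents=(ddf,))

    # analytic derivative of the interpolant w.r.t. the sample position;
    # zero where the position was clamped at the border
    inside = ((pos > 0.0) & (pos < lim[:, None, None, None])).astype(
        ddf.data.dtype)

    def bw(g):
        d_dx = (c1 - c0)
        c0y = c01 - c00
        c1y = c11 - c10
        d_dy = c0y * (1 - tx) + c1y * tx
        dz00 = c[0, 0, 1] - c[0, 0, 0]
        dz01 = c[0, 1, 1] - c[0, 1, 0]
        dz10 = c[1, 0, 1] - c[1, 0, 0]
        dz11 = c[1, 1, 1] - c[1, 1, 0]
        d_dz = ((dz00 * (1 - ty) + dz01 * ty) * (1 - tx)
                + (dz10 * (1 - ty) + dz11 * ty) * tx)
        grad = np.stack([d_dx, d_dy, d_dz]) * inside * g[None]
        ddf._accum(grad)
    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
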