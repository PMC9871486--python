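"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the perfusion GANs need: strided 2D
convolution and transposed convolution, 3D convolution with a strided time
axis, batch normalization, the usual activations, concatenation and the
elementwise pieces of the adversarial / L1 losses.  Gradients flow through a
tape of closures; ``backward`` runs a topological sweep.

Arrays keep whatever float dtype they are given (float32 for training,
float64 in gradient-check tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "conv3d", "batch_norm"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- elementwise algebra ----------------------------------------------
    def _unary(self, out_data, bw):
        out = Tensor(out_data)
        out._parents = (self,)
        out._backward = bw
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        return self._unary(-self.data, lambda g: self._accum(-g))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        return self + (-other)

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data)
            out._parents = (self, other)

            def bw(g):
                self._accum(_unbroadcast(g * other.data, self.data.shape))
                other._accum(_unbroadcast(g * self.data, other.data.shape))

            out._backward = bw
            return out
        c = other
        return self._unary(self.data * c, lambda g: self._accum(g * c))

    __rmul__ = __mul__

    def moveaxis(self, src: int, dst: int):
        return self._unary(
            np.ascontiguousarray(np.moveaxis(self.data, src, dst)),
            lambda g: self._accum(np.moveaxis(g, dst, src)),
        )

    def reshape(self, *shape):
        old = self.data.shape
        return self._unary(self.data.reshape(*shape), lambda g: self._accum(g.reshape(old)))

    def mean(self):
        n = self.data.size
        return self._unary(
            np.asarray(self.data.mean(), dtype=self.dtype),
            lambda g: self._accum(np.broadcast_to(g / n, self.data.shape).astype(self.dtype)),
        )

    def abs(self):
        s = np.sign(self.data)
        return self._unary(np.abs(self.data), lambda g: self._accum(g * s))

    def log(self):
        return self._unary(np.log(self.data), lambda g: self._accum(g / self.data))

    def clamp(self, lo, hi):
        mask = ((self.data > lo) & (self.data < hi)).astype(self.dtype)
        return self._unary(np.clip(self.data, lo, hi), lambda g: self._accum(g * mask))

    # -- activations -------------------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        scale = np.where(self.data > 0, 1.0, slope).astype(self.dtype)
        return self._unary(self.data * scale, lambda g: self._accum(g * scale))

    def relu(self):
        return self.leaky_relu(0.0)

    def tanh(self):
        y = np.tanh(self.data)
        return self._unary(y, lambda g: self._accum(g * (1.0 - y * y)))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, lambda g: self._accum(g * y * (1.0 - y)))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


# -- convolutions ----------------------------------------------------------
# All three use the same accumulate-over-kernel-offsets scheme: for each
# kernel offset the strided input slice lines up with the full output, and
# the per-offset contraction over channels is a single GEMM.  This keeps the
# peak memory at one activation map instead of an im2col buffer.

def _pad2(x, p):
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    s, p = stride, padding
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    xp = _pad2(x.data, p)
    y = np.zeros((n, o, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
            y += np.moveaxis(np.tensordot(w.data[:, :, i, j], xs, axes=(1, 1)), 0, 1)
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y)
    out._parents = parents

    def bw(g):
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
                dw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += np.moveaxis(
                    np.tensordot(w.data[:, :, i, j], g, axes=(0, 1)), 0, 1
                )
        w._accum(dw)
        x._accum(dxp[:, :, p : p + h, p : p + wd] if p else dxp)

    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed conv; weight layout (C_in, C_out, kh, kw), torch convention."""
    n, c, h, wd = x.data.shape
    c2, o, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv_transpose2d channel mismatch: input {c}, weight {c2}")
    s, p = stride, padding
    ho = (h - 1) * s - 2 * p + kh
    wo = (wd - 1) * s - 2 * p + kw
    yp = np.zeros((n, o, ho + 2 * p, wo + 2 * p), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            yp[:, :, i : i + h * s : s, j : j + wd * s : s] += np.moveaxis(
                np.tensordot(w.data[:, :, i, j], x.data, axes=(0, 1)), 0, 1
            )
    y = yp[:, :, p : p + ho, p : p + wo] if p else yp
    if b is not None:
        y = y + b.data.reshape(1, o, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(np.ascontiguousarray(y))
    out._parents = parents

    def bw(g):
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gp = _pad2(g, p)
        dx = np.zeros_like(x.data)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                gs = gp[:, :, i : i + h * s : s, j : j + wd * s : s]
                dx += np.moveaxis(np.tensordot(w.data[:, :, i, j], gs, axes=(1, 1)), 0, 1)
                dw[:, :, i, j] = np.tensordot(x.data, gs, axes=([0, 2, 3], [0, 2, 3]))
        x._accum(dx)
        w._accum(dw)

    out._backward = bw
    return out


# column buffers above this size fall back to the low-memory offset loop
_IM2COL_LIMIT_BYTES = 512 * 1024 * 1024


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: tuple[int, int, int] = (2, 1, 1),
    padding: tuple[int, int, int] = (1, 1, 1),
) -> Tensor:
    """3D convolution over (N, C, T, H, W); weight (O, C, kt, kh, kw).

    Time leads the spatial axes so that a strided time axis still leaves
    contiguous (H, W) blocks for the column gather/scatter.  Small inputs go
    through an im2col buffer (one GEMM forward, two backward, columns cached
    for the backward pass); large inputs use an offset-accumulation loop to
    keep memory bounded.
    """
    n, c, t, h, wd = x.data.shape
    o, c2, kt, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv3d channel mismatch: input {c}, weight {c2}")
    st, sh, sw = stride
    pt, ph, pw = padding
    to = (t + 2 * pt - kt) // st + 1
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    offsets = [(k, i, j) for k in range(kt) for i in range(kh) for j in range(kw)]
    n_off = len(offsets)

    def slc(k, i, j):
        return (slice(None), slice(None),
                slice(k, k + to * st, st), slice(i, i + ho * sh, sh), slice(j, j + wo * sw, sw))

    sp = to * ho * wo
    col_bytes = n_off * n * c * sp * x.data.dtype.itemsize
    parents = (x, w) + ((b,) if b is not None else ())
    # weight as (O, K*C): row blocks follow the offset loop order
    w_mat = np.ascontiguousarray(
        w.data.transpose(0, 2, 3, 4, 1).reshape(o, n_off * c)
    )

    if col_bytes <= _IM2COL_LIMIT_BYTES:
        cols = np.empty((n, n_off, c, to, ho, wo), dtype=x.dtype)
        for m, (k, i, j) in enumerate(offsets):
            cols[:, m] = xp[slc(k, i, j)]
        cols_mat = cols.reshape(n, n_off * c, sp)
        y = np.matmul(w_mat, cols_mat).reshape(n, o, to, ho, wo)
        if b is not None:
            y += b.data.reshape(1, o, 1, 1, 1)
        out = Tensor(y)
        out._parents = parents

        def bw(g):
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
            g_mat = g.reshape(n, o, sp)
            dw_mat = np.matmul(g_mat, cols_mat.transpose(0, 2, 1)).sum(axis=0)  # (O, K*C)
            w._accum(
                dw_mat.reshape(o, kt, kh, kw, c).transpose(0, 4, 1, 2, 3)
            )
            dcols = np.matmul(w_mat.T, g_mat).reshape(n, n_off, c, to, ho, wo)
            dxp = np.zeros_like(xp)
            for m, (k, i, j) in enumerate(offsets):
                dxp[slc(k, i, j)] += dcols[:, m]
            x._accum(dxp[:, :, pt : pt + t, ph : ph + h, pw : pw + wd])

        out._backward = bw
        return out

    y = np.zeros((n, o, to, ho, wo), dtype=x.dtype)
    for m, (k, i, j) in enumerate(offsets):
        wm = w_mat[:, m * c : (m + 1) * c]
        y += np.matmul(wm, xp[slc(k, i, j)].reshape(n, c, sp)).reshape(n, o, to, ho, wo)
    if b is not None:
        y += b.data.reshape(1, o, 1, 1, 1)
    out = Tensor(y)
    out._parents = parents

    def bw(g):
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        g_mat = g.reshape(n, o, sp)
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for m, (k, i, j) in enumerate(offsets):
            xs = np.ascontiguousarray(xp[slc(k, i, j)]).reshape(n, c, sp)
            dw[:, :, k, i, j] = np.matmul(g_mat, xs.transpose(0, 2, 1)).sum(axis=0)
            wm = w_mat[:, m * c : (m + 1) * c]
            dxp[slc(k, i, j)] += np.matmul(wm.T, g_mat).reshape(n, c, to, ho, wo)
        w._accum(dw)
        x._accum(dxp[:, :, pt : pt + t, ph : ph + h, pw : pw + wd])

    out._backward = bw
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over all axes except the channel axis (axis 1)."""
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = (1, x.data.shape[1]) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // x.data.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased running variance, as torch keeps it
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(bshape)) * inv.reshape(bshape)
    y = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
    out = Tensor(y.astype(x.dtype))
    out._parents = (x, gamma, beta)

    def bw(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        gamma._accum(dgamma)
        beta._accum(dbeta)
        gi = gamma.data * inv
        if training:
            m = x.data.size // x.data.shape[1]
            dx = gi.reshape(bshape) * (
                g - dbeta.reshape(bshape) / m - xhat * dgamma.reshape(bshape) / m
            )
        else:
            dx = gi.reshape(bshape) * g
        x._accum(dx.astype(x.dtype))

    out._backward = bw
    return out
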