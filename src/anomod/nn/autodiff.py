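"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the CNN–Transformer VAE: broadcasting arithmetic,
(batched) matmul, softmax, layer normalization, GELU, reductions, reshapes,
slicing, padding and concatenation.  Every op's gradient is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph mechanics ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        # Accumulation is never in-place, so sharing an upstream grad array
        # on first touch is safe.
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None):
        # Iterative DFS topological sort (a recursive closure would be
        # self-referential and turn every freed graph into cyclic garbage).
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------

    def _lift(self, x):
        if isinstance(x, Tensor):
            return x
        # match this tensor's dtype so python scalars don't upcast the graph
        return Tensor(np.asarray(x, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        if a.ndim > 2 and b.ndim == 2:
            # flatten batch dims: one large GEMM instead of many small ones
            a2 = a.reshape(-1, a.shape[-1])
            out = Tensor((a2 @ b).reshape(*a.shape[:-1], b.shape[1]),
                         parents=(self, other))

            def bw(g):
                g2 = np.asarray(g).reshape(-1, b.shape[1])
                if self.requires_grad:
                    self._accum((g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    other._accum(a2.T @ g2)

        else:
            out = Tensor(a @ b, parents=(self, other))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        e = np.exp(self.data)
        # closures capture plain arrays, never the output Tensor, so the
        # graph stays cycle-free and is freed by reference counting
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - y**2))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (self.data > 0)
        )
        return out

    def gelu(self):
        """Exact GELU x * Phi(x); derivative Phi(x) + x * phi(x)."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / 1.4142135623730951))
        out = Tensor(x * cdf, parents=(self,))

        def bw(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x**2) / 2.5066282746310002  # sqrt(2*pi)
                self._accum(g * (cdf + x * pdf))

        out._backward = bw
        return out

    def softmax(self):
        """Softmax over the last axis (numerically stabilized)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            y * (g - (g * y).sum(axis=-1, keepdims=True))
        )
        return out

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.asarray(g).reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self.requires_grad and self._accum(
            np.asarray(g).transpose(*inv)
        )
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        keys = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(k, (slice, int)) or k is Ellipsis for k in keys)

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            if basic:
                full[key] += g
            else:  # fancy indexing may repeat positions
                np.add.at(full, key, g)
            self._accum(full)

        out._backward = bw
        return out

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis with affine parameters."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = Tensor(xhat * gamma.data + beta.data, parents=(self, gamma, beta))

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if beta.requires_grad:
                beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
            if self.requires_grad:
                gy = g * gamma.data
                m1 = gy.mean(axis=-1, keepdims=True)
                m2 = (gy * xhat).mean(axis=-1, keepdims=True)
                self._accum(inv * (gy - m1 - xhat * m2))

        out._backward = bw
        return out


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(np.asarray(g), splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out._backward = bw
    return out


def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused x @ W + b for 2-D W, flattening any leading batch axes."""
    a = x.data
    a2 = a.reshape(-1, a.shape[-1])
    out = Tensor(
        (a2 @ W.data + b.data).reshape(*a.shape[:-1], W.data.shape[1]),
        parents=(x, W, b),
    )

    def bw(g):
        g2 = np.asarray(g).reshape(-1, W.data.shape[1])
        if b.requires_grad:
            b._accum(g2.sum(axis=0))
        if W.requires_grad:
            W._accum(a2.T @ g2)
        if x.requires_grad:
            x._accum((g2 @ W.data.T).reshape(a.shape))

    out._backward = bw
    return out


def conv1d_same(x: Tensor, W: Tensor, b: Tensor, kernel: int) -> Tensor:
    """Fused same-padding 1D convolution over axis 1 of (B, T, C).

    W is (C * kernel, C_out) with the kernel-offset blocks stacked along the
    first axis (offset-major, channel-minor); b is (C_out,).  One graph node
    instead of the pad/slice/concat/matmul composite.
    """
    half = kernel // 2
    B, T, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (half, half), (0, 0)))
    # cols[b, t, k*C + c] = xp[b, t + k, c]
    cols = np.concatenate([xp[:, k : k + T, :] for k in range(kernel)], axis=2)
    cols2 = cols.reshape(-1, C * kernel)
    out = Tensor(
        (cols2 @ W.data + b.data).reshape(B, T, -1), parents=(x, W, b)
    )

    def bw(g):
        g2 = np.asarray(g).reshape(-1, W.data.shape[1])
        if b.requires_grad:
            b._accum(g2.sum(axis=0))
        if W.requires_grad:
            W._accum(cols2.T @ g2)
        if x.requires_grad:
            dcols = (g2 @ W.data.T).reshape(B, T, kernel, C)
            dxp = np.zeros_like(xp)
            for k in range(kernel):
                dxp[:, k : k + T, :] += dcols[:, :, k, :]
            x._accum(dxp[:, half : half + T, :])

    out._backward = bw
    return out


def attention_core(q: Tensor, k: Tensor, v: Tensor, n_heads: int) -> Tensor:
    """Fused scaled-dot-product multi-head self-attention core.

    Inputs are the projected (B, T, D) query/key/value activations; the
    head split/merge, score scaling and softmax all live in this one node.
    """
    B, T, D = q.data.shape
    dh = D // n_heads
    scale = 1.0 / float(np.sqrt(dh))  # python float: no f32 -> f64 upcast

    def split(a):  # (B, T, D) -> (B, H, T, dh)
        return a.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q.data), split(k.data), split(v.data)
    scores = (qh @ kh.swapaxes(-1, -2)) * scale
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)  # (B, H, T, T)
    ctx = attn @ vh  # (B, H, T, dh)
    out = Tensor(
        ctx.transpose(0, 2, 1, 3).reshape(B, T, D), parents=(q, k, v)
    )

    def merge(a):  # (B, H, T, dh) -> (B, T, D)
        return a.transpose(0, 2, 1, 3).reshape(B, T, D)

    def bw(g):
        gh = np.asarray(g).reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
        if v.requires_grad:
            v._accum(merge(attn.swapaxes(-1, -2) @ gh))
        gattn = gh @ vh.swapaxes(-1, -2)
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores *= scale
        if q.requires_grad:
            q._accum(merge(gscores @ kh))
        if k.requires_grad:
            k._accum(merge(gscores.swapaxes(-1, -2) @ qh))

    out._backward = bw
    return out


def pad_axis1(t: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad along axis 1 (the time axis of a (B, T, C) tensor)."""
    width = [(0, 0)] * t.data.ndim
    width[1] = (before, after)
    out = Tensor(np.pad(t.data, width), parents=(t,))
    T = t.data.shape[1]
    out._backward = lambda g: t.requires_grad and t._accum(
        np.asarray(g)[:, before : before + T]
    )
    return out
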