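"""Neural-network building blocks on top of the autodiff engine.

Conventions: activations are (batch, time, channels); attention is over the
time axis; Transformer blocks use pre-layer-norm residual wiring, which
trains stably without a learning-rate warm-up.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, affine, attention_core, concat, conv1d_same, pad_axis1


class Module:
    """Parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def astype(self, dtype) -> "Module":
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.W = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return affine(x, self.W, self.b)


class Conv1d(Module):
    """Same-padding 1D convolution over the time axis, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd (same padding)")
        self.kernel = kernel
        bound = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.W = Tensor(
            rng.uniform(-bound, bound, size=(c_in * kernel, c_out)), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.W, self.b, self.kernel)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        ctx = attention_core(self.q(x), self.k(x), self.v(x), self.n_heads)
        return self.out(ctx)


def activate(x: Tensor, kind: str) -> Tensor:
    """relu (cheap, default for CPU training) or gelu."""
    return x.relu() if kind == "relu" else x.gelu()


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(activate(self.fc1(x), self.activation))


class TransformerBlock(Module):
    """Pre-LN Transformer block: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, n_heads: int, ff_mult: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_mult * dim, rng, activation=activation)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff(self.ln2(x))


def sinusoidal_positions(T: int, D: int) -> np.ndarray:
    """Standard fixed sinusoidal positional encoding table (T, D)."""
    pos = np.arange(T)[:, None]
    i = np.arange(D)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / D)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table
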