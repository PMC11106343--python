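"""Neural network layers built on the autograd engine.

Initialization follows Glorot-uniform for dense/embedding weights.  All layers
share a ``Module`` base that collects parameters recursively and carries the
training/inference flag used by dropout.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, dropout, embedding


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Dense(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.weight = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gain + self.shift


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n_vocab: int, dim: int):
        self.weight = Tensor(glorot(rng, n_vocab, dim), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Sinusoidal position code, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class MultiHeadAttention(Module):
    """Scaled dot-product attention; ``dim_kv`` allows cross-attention where
    keys/values come from an encoder of a different width."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int, dim_kv: int | None = None):
        if dim % n_heads != 0:
            raise ValueError(f"model width {dim} not divisible by {n_heads} heads")
        dim_kv = dim_kv or dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.w_q = Dense(rng, dim, dim)
        self.w_k = Dense(rng, dim_kv, dim)
        self.w_v = Dense(rng, dim_kv, dim)
        self.w_o = Dense(rng, dim, dim)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, keyvalue: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, tq, _ = query.shape
        q = self._split(self.w_q(query))
        k = self._split(self.w_k(keyvalue))
        v = self._split(self.w_v(keyvalue))
        scores = (q @ k.swapaxes(-1, -2)) * (self.d_head**-0.5)
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, tq, self.n_heads * self.d_head)
        return self.w_o(out)


def causal_mask(length: int) -> np.ndarray:
    """Additive mask blocking attention to future positions."""
    return np.triu(np.full((1, 1, length, length), -1e9), k=1)


class FeedForward(Module):
    def __init__(self, rng: np.random.Generator, dim: int, inner: int):
        self.lin1 = Dense(rng, dim, inner)
        self.lin2 = Dense(rng, inner, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention and feed-forward sub-layers,
    each wrapped in residual + layer normalization."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int, inner: int, drop: float):
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.ff = FeedForward(rng, dim, inner)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.drop = drop

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        x = self.norm1(x + dropout(self.attn(x, x), self.drop, rng, training))
        x = self.norm2(x + dropout(self.ff(x), self.drop, rng, training))
        return x


class TransformerDecoderLayer(Module):
    """Masked self-attention, cross-attention over the encoder output
    (keys/values), then feed-forward; residual + layer-norm around each."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int, inner: int, drop: float, dim_enc: int):
        self.self_attn = MultiHeadAttention(rng, dim, n_heads)
        self.cross_attn = MultiHeadAttention(rng, dim, n_heads, dim_kv=dim_enc)
        self.ff = FeedForward(rng, dim, inner)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.drop = drop

    def __call__(self, x: Tensor, enc: Tensor, mask: np.ndarray,
                 rng: np.random.Generator, training: bool) -> Tensor:
        x = self.norm1(x + dropout(self.self_attn(x, x, mask), self.drop, rng, training))
        x = self.norm2(x + dropout(self.cross_attn(x, enc), self.drop, rng, training))
        x = self.norm3(x + dropout(self.ff(x), self.drop, rng, training))
        return x


class LSTM(Module):
    """Single-layer LSTM scanning axis 1 of a (B, T, D) input."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        # gates ordered i, f, g, o in one fused weight
        self.w = Tensor(glorot(rng, n_in + n_hidden, 4 * n_hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * n_hidden), requires_grad=True)
        self.b.data[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = concat([x_t, h], axis=-1) @ self.w + self.b
        nh = self.n_hidden
        i = z[:, 0 * nh : 1 * nh].sigmoid()
        f = z[:, 1 * nh : 2 * nh].sigmoid()
        g = z[:, 2 * nh : 3 * nh].tanh()
        o = z[:, 3 * nh : 4 * nh].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        return h, c

    def __call__(self, x: Tensor, h0: Tensor | None = None, c0: Tensor | None = None,
                 reverse: bool = False) -> tuple[Tensor, Tensor, Tensor]:
        b, t, _ = x.shape
        h = h0 if h0 is not None else Tensor(np.zeros((b, self.n_hidden)))
        c = c0 if c0 is not None else Tensor(np.zeros((b, self.n_hidden)))
        steps = range(t - 1, -1, -1) if reverse else range(t)
        outputs: list[Tensor] = [None] * t  # type: ignore[list-item]
        for ti in steps:
            h, c = self.step(x[:, ti, :], h, c)
            outputs[ti] = h
        seq = concat([o.reshape(b, 1, self.n_hidden) for o in outputs], axis=1)
        return seq, h, c


class BiLSTM(Module):
    """Bidirectional LSTM; forward/backward outputs concatenated."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden_per_dir: int):
        self.fwd = LSTM(rng, n_in, n_hidden_per_dir)
        self.bwd = LSTM(rng, n_in, n_hidden_per_dir)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        seq_f, h_f, _ = self.fwd(x)
        seq_b, h_b, _ = self.bwd(x, reverse=True)
        return concat([seq_f, seq_b], axis=-1), concat([h_f, h_b], axis=-1)
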