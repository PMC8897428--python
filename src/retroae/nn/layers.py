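"""Pre-norm transformer encoder–decoder built on the local autograd.

Architecture notes: layer normalization is applied *before* each
self-attention, cross-attention and feed-forward sublayer (pre-norm), and
the encoder and decoder outputs are normalized once more at the end.
Token embeddings are shared between source and target (they index the
same AE vocabulary); the sinusoidal positional encoding is optional
because the AE representation is itself permutation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

NEG_INF = -1e9


@dataclass
class Ctx:
    """Per-forward-pass context: training mode, dropout rate, RNG."""

    train: bool
    dropout: float
    rng: np.random.Generator


def sinusoidal_encoding(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = ag.parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = ag.parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.W), self.b)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = ag.parameter(np.ones(dim))
        self.bias = ag.parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gain, self.bias)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` parallel heads.

    The most recent attention probabilities are stashed on
    ``last_weights`` (shape batch × heads × n_query × n_key) when the
    forward pass is called with ``record=True``.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"model_dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor, batch: int, n: int) -> Tensor:
        x = ag.reshape(x, (batch, n, self.n_heads, self.d_head))
        return ag.transpose(x, (0, 2, 1, 3))  # B,H,T,dh

    def __call__(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        additive_mask: np.ndarray | None,
        ctx: Ctx,
        record: bool = False,
    ) -> Tensor:
        batch, n_q = query.shape[0], query.shape[1]
        n_k = key.shape[1]
        q = self._split(self.wq(query), batch, n_q)
        k = self._split(self.wk(key), batch, n_k)
        v = self._split(self.wv(value), batch, n_k)
        scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(self.d_head))
        weights = ag.softmax(scores, additive_mask)
        if record:
            self.last_weights = weights.data.copy()
        weights = ag.dropout(weights, ctx.dropout, ctx.rng, ctx.train)
        out = ag.matmul(weights, v)  # B,H,Tq,dh
        out = ag.transpose(out, (0, 2, 1, 3))
        out = ag.reshape(out, (batch, n_q, self.dim))
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, ff_dim: int, rng: np.random.Generator):
        self.w1 = Linear(dim, ff_dim, rng)
        self.w2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor, ctx: Ctx) -> Tensor:
        h = ag.relu(self.w1(x))
        h = ag.dropout(h, ctx.dropout, ctx.rng, ctx.train)
        return self.w2(h)


class EncoderLayer(Module):
    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_dim, rng)

    def __call__(self, x: Tensor, src_mask: np.ndarray | None, ctx: Ctx) -> Tensor:
        h = self.norm1(x)
        x = ag.add(x, ag.dropout(self.attn(h, h, h, src_mask, ctx), ctx.dropout, ctx.rng, ctx.train))
        h = self.norm2(x)
        return ag.add(x, ag.dropout(self.ff(h, ctx), ctx.dropout, ctx.rng, ctx.train))


class DecoderLayer(Module):
    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.self_attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm3 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_dim, rng)

    def __call__(
        self,
        x: Tensor,
        memory: Tensor,
        tgt_mask: np.ndarray | None,
        mem_mask: np.ndarray | None,
        ctx: Ctx,
        record: bool = False,
    ) -> Tensor:
        h = self.norm1(x)
        x = ag.add(x, ag.dropout(self.self_attn(h, h, h, tgt_mask, ctx), ctx.dropout, ctx.rng, ctx.train))
        h = self.norm2(x)
        x = ag.add(
            x,
            ag.dropout(
                self.cross_attn(h, memory, memory, mem_mask, ctx, record=record),
                ctx.dropout, ctx.rng, ctx.train,
            ),
        )
        h = self.norm3(x)
        return ag.add(x, ag.dropout(self.ff(h, ctx), ctx.dropout, ctx.rng, ctx.train))


class Transformer(Module):
    """Encoder–decoder over integer token sequences (0 is padding)."""

    def __init__(
        self,
        n_tokens: int,
        n_layers: int = 2,
        n_heads: int = 4,
        model_dim: int = 64,
        ff_dim: int = 256,
        max_len: int = 104,
        positional_encoding: bool = True,
        tie_embedding: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.n_tokens = n_tokens
        self.model_dim = model_dim
        self.tie_embedding = tie_embedding
        self.embed = ag.parameter(rng.normal(0.0, model_dim ** -0.5, size=(n_tokens, model_dim)))
        self.pos = sinusoidal_encoding(max_len, model_dim) if positional_encoding else None
        self.enc_layers = [EncoderLayer(model_dim, n_heads, ff_dim, rng) for _ in range(n_layers)]
        self.dec_layers = [DecoderLayer(model_dim, n_heads, ff_dim, rng) for _ in range(n_layers)]
        self.enc_norm = LayerNorm(model_dim)
        self.dec_norm = LayerNorm(model_dim)
        if tie_embedding:
            # output logits share the token embedding (transposed), a
            # standard weight tying that speeds up copy-like learning
            self.out_bias = ag.parameter(np.zeros(n_tokens))
            self.out_proj = lambda x: ag.add(
                ag.matmul(x, ag.transpose(self.embed, (1, 0))), self.out_bias
            )
        else:
            self.out_proj = Linear(model_dim, n_tokens, rng)

    # -- masks --------------------------------------------------------------
    @staticmethod
    def padding_mask(ids: np.ndarray) -> np.ndarray:
        """Additive key-padding mask, shape (B, 1, 1, T)."""
        return np.where(ids == 0, NEG_INF, 0.0)[:, None, None, :]

    @staticmethod
    def causal_mask(n: int) -> np.ndarray:
        return np.where(np.triu(np.ones((n, n)), k=1) > 0, NEG_INF, 0.0)[None, None]

    # -- forward ------------------------------------------------------------
    def _embed(self, ids: np.ndarray, ctx: Ctx) -> Tensor:
        x = ag.scale(ag.embedding(self.embed, ids), np.sqrt(self.model_dim))
        if self.pos is not None:
            x = ag.add(x, Tensor(self.pos[: ids.shape[1]]))
        return ag.dropout(x, ctx.dropout, ctx.rng, ctx.train)

    def encode(self, src_ids: np.ndarray, ctx: Ctx) -> Tensor:
        mask = self.padding_mask(src_ids)
        x = self._embed(src_ids, ctx)
        for layer in self.enc_layers:
            x = layer(x, mask, ctx)
        return self.enc_norm(x)

    def decode(
        self,
        tgt_ids: np.ndarray,
        memory: Tensor,
        src_ids: np.ndarray,
        ctx: Ctx,
        record_attention: bool = False,
    ) -> Tensor:
        n = tgt_ids.shape[1]
        tgt_mask = self.causal_mask(n) + self.padding_mask(tgt_ids)
        mem_mask = self.padding_mask(src_ids)
        x = self._embed(tgt_ids, ctx)
        for layer in self.dec_layers:
            x = layer(x, memory, tgt_mask, mem_mask, ctx, record=record_attention)
        x = self.dec_norm(x)
        return self.out_proj(x)

    def forward(
        self,
        src_ids: np.ndarray,
        tgt_in: np.ndarray,
        ctx: Ctx,
        record_attention: bool = False,
    ) -> Tensor:
        memory = self.encode(src_ids, ctx)
        return self.decode(tgt_in, memory, src_ids, ctx, record_attention)

    def cross_attention_weights(self) -> list[np.ndarray]:
        """Per-layer cross-attention weights of the most recent recorded pass."""
        return [layer.cross_attn.last_weights for layer in self.dec_layers]

    # -- persistence ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            saved = arrays[f"p{i}"]
            if saved.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at parameter {i}")
            p.data = saved.copy()
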