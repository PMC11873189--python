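"""Neural building blocks for the key/value tabular encoder.

The encoder follows the original post-norm transformer block (multi-head
scaled dot-product attention, residual + layer norm, position-wise
feed-forward, residual + layer norm) but deliberately carries **no
positional encoding**: a patient's features form a set, so the survival
score must not depend on the order in which they are presented. Input
embeddings are the sum of a name-lookup embedding and a linear projection
of the scalar value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["ModelConfig", "softmax", "Dense", "LayerNorm", "EncoderLayer",
           "TabularEncoder", "init_weight"]

NEG_INF = -1e9  # attention logit for PAD columns


@dataclass
class ModelConfig:
    """Architecture hyperparameters (serialized with every checkpoint)."""

    d_k: int = 128          # embedding dimension
    n_layers: int = 4       # encoder blocks
    n_heads: int = 4        # attention heads (d_k divisible by n_heads)
    ff_dim: int | None = None  # feed-forward width, default 4*d_k
    dropout: float = 0.1
    vocab_size: int = 0     # filled from the Vocabulary
    max_len: int = 0        # filled from the max-length policy
    sigma: float = 0.1      # sigmoid smoothing of the concordance loss
    mask_fraction: float = 0.2
    alpha_names: float = 1.0
    alpha_values: float = 0.01

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 4 * self.d_k
        if self.d_k % self.n_heads != 0:
            raise ValueError("d_k must be divisible by n_heads")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def init_weight(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal initialization (|z| <= 2 std), BERT-style."""
    w = rng.normal(0.0, std, size=shape)
    bad = np.abs(w) > 2 * std
    while bad.any():
        w[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(w) > 2 * std
    return w


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops."""
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant, no grad
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Module:
    """Tiny parameter container (named parameters for checkpointing)."""

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                out[name] = attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        self.W = Parameter(init_weight(rng, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention over feature positions.

    PAD columns are masked to a large negative logit before the softmax so
    each attention row is a distribution over observed features only.
    """

    def __init__(self, rng, d_k: int, n_heads: int):
        self.n_heads = n_heads
        self.d_head = d_k // n_heads
        self.Wq = Dense(rng, d_k, d_k, bias=False)
        self.Wk = Dense(rng, d_k, d_k, bias=False)
        self.Wv = Dense(rng, d_k, d_k, bias=False)
        self.Wo = Dense(rng, d_k, d_k, bias=False)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        # (B, L, d_k) -> (B, H, L, d_head)
        return x.reshape(B, L, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, x: Tensor, pad_mask: np.ndarray
                 ) -> tuple[Tensor, np.ndarray]:
        B, L, _ = x.shape
        q = self._split(self.Wq(x), B, L)
        k = self._split(self.Wk(x), B, L)
        v = self._split(self.Wv(x), B, L)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        col_mask = pad_mask[:, None, None, :]  # (B,1,1,L) broadcast over rows
        scores = scores.masked_fill(np.broadcast_to(col_mask, scores.shape), NEG_INF)
        attn = softmax(scores, axis=-1)
        out = attn @ v  # (B, H, L, d_head)
        out = out.swapaxes(1, 2).reshape(B, L, self.n_heads * self.d_head)
        return self.Wo(out), attn.data


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when p=0 or no rng (inference)."""
    if p <= 0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class EncoderLayer(Module):
    def __init__(self, rng, d_k: int, n_heads: int, ff_dim: int):
        self.attn = MultiHeadAttention(rng, d_k, n_heads)
        self.norm1 = LayerNorm(d_k)
        self.ff1 = Dense(rng, d_k, ff_dim)
        self.ff2 = Dense(rng, ff_dim, d_k)
        self.norm2 = LayerNorm(d_k)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, p: float = 0.0,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, np.ndarray]:
        a, attn = self.attn(x, pad_mask)
        x = self.norm1(x + _dropout(a, p, rng))
        f = self.ff2(self.ff1(x).relu())
        x = self.norm2(x + _dropout(f, p, rng))
        return x, attn


@dataclass
class EmbeddingSet:
    """Per-position output embeddings for one encoded batch."""

    P: np.ndarray               # (B, L, d_k) last-layer embeddings
    pad_mask: np.ndarray        # (B, L)
    token_ids: np.ndarray       # (B, L)
    attention: list[np.ndarray] = field(default_factory=list)

    @property
    def P_task(self) -> np.ndarray:
        """Outcome embedding (TASK/CLS position), shape (B, d_k)."""
        return self.P[:, 0, :]


class TabularEncoder(Module):
    """Name+value input embedding followed by the encoder stack.

    ``embed_inputs`` returns E = E_name + E_value where E_name is a token
    lookup and E_value a shared linear projection of the scalar value.
    ``encode`` runs the block stack and returns per-position embeddings
    plus per-layer attention matrices.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.name_emb = Parameter(init_weight(rng, (config.vocab_size, config.d_k)))
        self.value_proj = Dense(rng, 1, config.d_k)
        self.layers = [EncoderLayer(rng, config.d_k, config.n_heads, config.ff_dim)
                       for _ in range(config.n_layers)]

    def embed_inputs(self, token_ids: np.ndarray, values: np.ndarray) -> Tensor:
        if token_ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary range")
        e_name = self.name_emb.take_rows(token_ids)          # (B, L, d_k)
        vals = Tensor(values[..., None])                     # (B, L, 1)
        e_val = self.value_proj(vals)                        # (B, L, d_k)
        return e_name + e_val

    def encode(self, E: Tensor, pad_mask: np.ndarray,
               collect_attention: bool = False,
               dropout_rng: np.random.Generator | None = None
               ) -> tuple[Tensor, list[np.ndarray]]:
        x = E
        p = self.config.dropout if dropout_rng is not None else 0.0
        attns: list[np.ndarray] = []
        for i, layer in enumerate(self.layers):
            x, attn = layer(x, pad_mask, p=p, rng=dropout_rng)
            if np.isnan(x.data).any():
                raise FloatingPointError(f"NaN activations in encoder layer {i}")
            if collect_attention:
                attns.append(attn)
        return x, attns

    def forward(self, batch, collect_attention: bool = False,
                dropout_rng: np.random.Generator | None = None
                ) -> tuple[Tensor, EmbeddingSet]:
        E = self.embed_inputs(batch.token_ids, batch.values)
        P, attns = self.encode(E, batch.pad_mask, collect_attention,
                               dropout_rng=dropout_rng)
        eset = EmbeddingSet(P=P.data, pad_mask=batch.pad_mask,
                            token_ids=batch.token_ids, attention=attns)
        return P, eset
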