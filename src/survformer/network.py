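"""The full network: tabular encoder plus task heads, with checkpointing.

Heads:
  * survival head — a single linear neuron without bias on the TASK
    (CLS) output embedding; its scalar output beta is the predicted
    survival score (higher = longer predicted survival).
  * masked-name head — dense layer + softmax over the feature-name
    vocabulary (reserved tokens excluded).
  * masked-value head — dense linear layer predicting the masked scalar.

Checkpoints are directories holding config.json, vocabulary.json and
weights.npz; loading validates that config and vocabulary match.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .cohort import EncodedBatch, Vocabulary
from .layers import Dense, EmbeddingSet, ModelConfig, Module, TabularEncoder

__all__ = ["SurvivalTransformerNet"]


class SurvivalTransformerNet(Module):
    def __init__(self, config: ModelConfig, vocab: Vocabulary,
                 seed: int = 0):
        if config.vocab_size != len(vocab):
            config.vocab_size = len(vocab)
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        self.encoder = TabularEncoder(config, rng)
        self.surv_head = Dense(rng, config.d_k, 1, bias=False)
        self.name_head = Dense(rng, config.d_k, vocab.n_features)
        self.value_head = Dense(rng, config.d_k, 1)

    # -- forward passes --------------------------------------------------
    def forward(self, batch: EncodedBatch, collect_attention: bool = False,
                dropout_rng: np.random.Generator | None = None
                ) -> tuple[Tensor, EmbeddingSet]:
        return self.encoder.forward(batch, collect_attention, dropout_rng)

    def survival_scores(self, batch: EncodedBatch,
                        dropout_rng: np.random.Generator | None = None
                        ) -> tuple[Tensor, EmbeddingSet]:
        """beta = P_task . W^T for every row of the batch."""
        P, eset = self.forward(batch, dropout_rng=dropout_rng)
        B = batch.token_ids.shape[0]
        p_task = P[:, 0, :]                      # (B, d_k)
        beta = self.surv_head(p_task).reshape(B)
        return beta, eset

    def masked_heads(self, P: Tensor, mask_positions: np.ndarray
                     ) -> tuple[Tensor, Tensor]:
        """Name logits and value estimates at the masked positions.

        ``P`` is the (B, L, d_k) output tensor; ``mask_positions`` a
        boolean (B, L) array. Returns ((M, n_features) logits, (M,)
        value estimates) in row-major masked order.
        """
        if not mask_positions.any():
            raise ValueError("no masked positions")
        idx = np.nonzero(mask_positions)
        p_masked = P[idx]                        # (M, d_k)
        logits = self.name_head(p_masked)
        values = self.value_head(p_masked).reshape(p_masked.shape[0])
        return logits, values

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(self.config.to_dict(), indent=1))
        (d / "vocabulary.json").write_text(self.vocab.to_json())
        np.savez(d / "weights.npz",
                 **{k: p.data for k, p in self.parameters().items()})

    @classmethod
    def load(cls, directory) -> "SurvivalTransformerNet":
        d = Path(directory)
        config = ModelConfig.from_dict(json.loads((d / "config.json").read_text()))
        vocab = Vocabulary.from_json((d / "vocabulary.json").read_text())
        net = cls(config, vocab, seed=0)
        with np.load(d / "weights.npz") as data:
            params = net.parameters()
            if set(params) != set(data.files):
                raise ValueError("checkpoint weights do not match architecture")
            for k, p in params.items():
                if p.data.shape != data[k].shape:
                    raise ValueError(f"shape mismatch for parameter {k}")
                p.data = data[k].copy()
        return net

    def copy_weights_from(self, other: "SurvivalTransformerNet",
                          encoder_only: bool = False) -> None:
        """Warm-start from another net (e.g. pretrained encoder)."""
        if other.vocab.id_to_name != self.vocab.id_to_name:
            raise ValueError("vocabulary mismatch between models")
        src = other.parameters()
        for k, p in self.parameters().items():
            if encoder_only and not k.startswith("encoder."):
                continue
            p.data = src[k].data.copy()
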