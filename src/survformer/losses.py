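"""Training objectives and the concordance metric.

The survival objective is a smooth surrogate of Harrell's C-index:

    L = sum_{i,j} w_ij * sigmoid((beta_i - beta_j) / sigma)
    w_ij = Delta_i * I(T_i < T_j) / sum_{i,j} Delta_i * I(T_i < T_j)

written here with the sigmoid of (beta_j - beta_i)/sigma in the logistic
form 1/(1+exp(.)), so a *concordant* pair (the shorter-lived patient i
scoring lower, beta_i < beta_j) contributes ~0 and a discordant pair ~1.
Minimizing L therefore pushes predicted scores toward the observed
ranking of survival times; as sigma -> 0 the loss approaches
1 - C-index on tie-free data.

Masked pretraining hides a fraction of feature *names* (values stay
visible) and scores their reconstruction with
alpha_names * cross-entropy + alpha_values * MSE, averaged per masked slot.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .cohort import Vocabulary
from .layers import softmax

__all__ = ["survival_loss", "c_index", "mask_features", "pretrain_loss",
           "NoComparablePairs", "comparable_pair_weights"]


class NoComparablePairs(ValueError):
    """Raised when a batch contains no usable (event, longer-time) pair."""


def comparable_pair_weights(T: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Normalized pair weights w_ij = Delta_i I(T_i<T_j) / sum(...).

    Pairs with tied times are non-comparable and receive weight 0.
    """
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=float)
    comparable = delta[:, None] * (T[:, None] < T[None, :])
    total = comparable.sum()
    if total == 0:
        raise NoComparablePairs("no comparable pairs in batch")
    return comparable / total


def survival_loss(beta: Tensor | np.ndarray, T: np.ndarray, delta: np.ndarray,
                  sigma: float = 0.1) -> Tensor:
    """Differentiable sigmoid approximation of 1 - C-index.

    Returns a scalar :class:`Tensor` in (0, 1); 0.5 exactly when all
    scores are equal.
    """
    if not isinstance(beta, Tensor):
        beta = Tensor(np.asarray(beta, dtype=float))
    w = comparable_pair_weights(T, delta)
    n = beta.data.shape[0]
    bi = beta.reshape(n, 1)
    bj = beta.reshape(1, n)
    # term_ij = 1 / (1 + exp((beta_j - beta_i)/sigma)): ~0 when beta_i << beta_j
    z = (bj - bi) * (1.0 / sigma)
    term = 1.0 / (z.exp() + 1.0)
    return (term * Tensor(w)).sum()


def c_index(beta: np.ndarray, T: np.ndarray, delta: np.ndarray) -> float:
    """Harrell's concordance index with half credit for tied scores.

    A pair (i, j) is comparable when patient i died (delta_i=1) and
    T_i < T_j; it is concordant when beta_i < beta_j (lower score =
    shorter predicted survival). Tied-time pairs are non-comparable.
    """
    beta = np.asarray(beta, dtype=float)
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    comparable = (delta[:, None] == 1) & (T[:, None] < T[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        raise NoComparablePairs("no comparable pairs")
    concordant = comparable & (beta[:, None] < beta[None, :])
    tied = comparable & (beta[:, None] == beta[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def mask_features(token_ids: np.ndarray, pad_mask: np.ndarray,
                  mask_fraction: float, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replace a fraction of feature-name tokens with [MASK].

    Values are left untouched (they remain visible inputs). TASK and PAD
    positions are never masked; ceil(mask_fraction * count) names are
    masked per row, at least one when the row has any feature.

    Returns (masked_token_ids, mask_positions, original_ids) where
    ``mask_positions`` is a boolean (B, L) array of masked slots.
    """
    if not 0 < mask_fraction < 1:
        raise ValueError("mask_fraction must be in (0, 1)")
    masked = token_ids.copy()
    positions = np.zeros_like(pad_mask)
    for b in range(token_ids.shape[0]):
        feat_slots = np.flatnonzero(~pad_mask[b])
        feat_slots = feat_slots[token_ids[b, feat_slots] >= Vocabulary.N_RESERVED]
        if len(feat_slots) == 0:
            continue
        k = int(np.ceil(mask_fraction * len(feat_slots)))
        chosen = rng.choice(feat_slots, size=k, replace=False)
        masked[b, chosen] = Vocabulary.MASK
        positions[b, chosen] = True
    return masked, positions, token_ids


def pretrain_loss(name_logits: Tensor, value_estimates: Tensor,
                  target_ids: np.ndarray, target_values: np.ndarray,
                  alpha_names: float = 1.0, alpha_values: float = 0.01
                  ) -> tuple[Tensor, float, float]:
    """Weighted masked-reconstruction loss, averaged per masked slot.

    ``name_logits``: (M, n_feature_names) raw scores over the feature
    vocabulary (reserved tokens excluded); ``target_ids``: (M,) class
    indices into that same feature-name space; ``value_estimates``: (M,)
    or (M, 1) scalar predictions of the masked values.

    Returns (loss, name_loss_value, value_loss_value).
    """
    M = name_logits.shape[0]
    if M == 0:
        raise ValueError("pretraining requires at least one masked position")
    probs = softmax(name_logits, axis=-1)
    picked = probs[np.arange(M), np.asarray(target_ids, dtype=int)]
    name_loss = -(picked.log().mean())
    ve = value_estimates.reshape(M)
    diff = ve - Tensor(np.asarray(target_values, dtype=float))
    value_loss = (diff * diff).mean()
    total = name_loss * alpha_names + value_loss * alpha_values
    return total, float(name_loss.data), float(value_loss.data)
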