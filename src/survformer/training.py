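"""Learning strategies, split management and training loops.

Three strategies are supported: *direct* (train the survival task from
scratch), *gradual* (masked-feature pretraining on the same cohort, then
survival fine-tuning) and *transfer* (pretraining on a different, usually
larger, cohort). Evaluation uses repeated random 80/20 train/test splits
(10 by default) with per-epoch test C-index learning curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, EncodedBatch, Vocabulary, encode_cohort, sample_and_pad
from .layers import ModelConfig
from .losses import (NoComparablePairs, c_index, mask_features, pretrain_loss,
                     survival_loss)
from .network import SurvivalTransformerNet
from .optim import Adam

__all__ = ["TrainPlan", "make_splits", "save_splits", "load_splits",
           "pretrain", "fine_tune", "predict_scores", "stratify_quartiles",
           "FitHistory"]

#: number of seeded subsamples averaged at inference when a record has
#: more features than fit in the input length
INFERENCE_SAMPLES = 20


@dataclass
class TrainPlan:
    """What to train, for how long, and on which splits."""

    strategy: str = "direct"          # direct | gradual | transfer
    pretrain_iters: int = 2000
    finetune_epochs: int = 30
    n_splits: int = 10
    train_frac: float = 0.8
    batch_size: int = 64
    lr: float = 1e-3
    clip_norm: float = 1.0
    seed: int = 0
    eval_every: int = 1               # epochs between learning-curve points

    def __post_init__(self):
        if self.strategy not in ("direct", "gradual", "transfer"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FitHistory:
    """Per-split learning curve: (epoch, test C-index) pairs."""

    epochs: list[int] = field(default_factory=list)
    test_c_index: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)


# ----------------------------------------------------------------------
# splits

def make_splits(n: int, n_splits: int = 10, train_frac: float = 0.8,
                seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random train/test partitions of range(n)."""
    if train_frac >= 1.0:
        warnings.warn("train_frac >= 1: test sets will be empty")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    out = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def save_splits(splits, path) -> None:
    payload = [{"train": tr.tolist(), "test": te.tolist()} for tr, te in splits]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_splits(path) -> list[tuple[np.ndarray, np.ndarray]]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return [(np.asarray(d["train"]), np.asarray(d["test"])) for d in payload]


# ----------------------------------------------------------------------
# training loops

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def pretrain(cohort: Cohort, config: ModelConfig, vocab: Vocabulary,
             L: int, iters: int, batch_size: int = 64, lr: float = 1e-3,
             seed: int = 0, net: SurvivalTransformerNet | None = None,
             log_every: int = 0) -> tuple[SurvivalTransformerNet, list[dict]]:
    """Masked-feature self-supervised pretraining.

    Each optimizer step draws a fresh batch, resamples each record's
    features, masks a fraction of names and minimizes the weighted
    name/value reconstruction loss. Returns the net and a log of loss
    components.
    """
    if net is None:
        net = SurvivalTransformerNet(config, vocab, seed=seed)
    if iters == 0:
        return net, []
    rng = np.random.default_rng(seed + 1)
    opt = Adam(net.parameters(), lr=lr)
    records = list(cohort)
    log = []
    n = len(records)
    step = 0
    while step < iters:
        for idx in _batches(n, batch_size, rng):
            if step >= iters:
                break
            batch_records = [records[i] for i in idx]
            rows = [sample_and_pad(r, L, vocab, rng) for r in batch_records]
            batch = EncodedBatch(
                token_ids=np.stack([r[0] for r in rows]),
                values=np.stack([r[1] for r in rows]),
                pad_mask=np.stack([r[2] for r in rows]))
            masked_ids, positions, original = mask_features(
                batch.token_ids, batch.pad_mask, config.mask_fraction, rng)
            if not positions.any():
                step += 1
                continue
            masked_batch = EncodedBatch(masked_ids, batch.values, batch.pad_mask)
            P, _ = net.forward(masked_batch, dropout_rng=rng)
            logits, value_est = net.masked_heads(P, positions)
            target_ids = original[positions] - Vocabulary.N_RESERVED
            target_vals = batch.values[positions]
            loss, name_l, value_l = pretrain_loss(
                logits, value_est, target_ids, target_vals,
                config.alpha_names, config.alpha_values)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"pretraining diverged at step {step}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if log_every and step % log_every == 0:
                log.append({"step": step, "loss": float(loss.data),
                            "name_loss": name_l, "value_loss": value_l})
            step += 1
    return net, log


def fine_tune(net: SurvivalTransformerNet, cohort: Cohort,
              train_idx: np.ndarray, test_idx: np.ndarray, L: int,
              epochs: int, batch_size: int = 64, lr: float = 1e-3,
              sigma: float | None = None, seed: int = 0,
              eval_every: int = 1) -> FitHistory:
    """Optimize the survival loss on one train split, tracking the test
    C-index per epoch. Modifies ``net`` in place."""
    vocab = net.vocab
    sigma = net.config.sigma if sigma is None else sigma
    rng = np.random.default_rng(seed + 2)
    opt = Adam(net.parameters(), lr=lr)
    train_records = [cohort.records[i] for i in train_idx]
    T = np.array([r.time for r in train_records])
    delta = np.array([r.event for r in train_records])
    test_cohort = cohort[list(test_idx)] if len(test_idx) else None
    history = FitHistory()
    n = len(train_records)
    for epoch in range(epochs):
        epoch_losses = []
        for idx in _batches(n, batch_size, rng):
            recs = [train_records[i] for i in idx]
            rows = [sample_and_pad(r, L, vocab, rng) for r in recs]
            batch = EncodedBatch(
                token_ids=np.stack([r[0] for r in rows]),
                values=np.stack([r[1] for r in rows]),
                pad_mask=np.stack([r[2] for r in rows]))
            beta, _ = net.survival_scores(batch, dropout_rng=rng)
            try:
                loss = survival_loss(beta, T[idx], delta[idx], sigma)
            except NoComparablePairs:
                warnings.warn("batch without comparable pairs skipped")
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        if (epoch + 1) % eval_every == 0 and test_cohort is not None:
            beta_test = predict_scores(net, test_cohort, L)
            try:
                ci = c_index(beta_test, test_cohort.times, test_cohort.events)
            except NoComparablePairs:
                ci = float("nan")
            history.epochs.append(epoch + 1)
            history.test_c_index.append(ci)
            history.train_loss.append(float(np.mean(epoch_losses))
                                      if epoch_losses else float("nan"))
    return history


def predict_scores(net: SurvivalTransformerNet, cohort: Cohort,
                   L: int | None = None) -> np.ndarray:
    """Deterministic per-patient survival scores.

    Records whose feature count fits within L-1 are encoded exactly once
    (all features, id order). Longer records are scored as the average
    over a fixed set of seeded feature subsamples, which removes
    prediction nondeterminism while honoring the max-length policy.
    """
    L = net.config.max_len if L is None else L
    vocab = net.vocab
    simple, long_recs = [], []
    for i, r in enumerate(cohort):
        (long_recs if r.n_features > L - 1 else simple).append(i)
    beta = np.empty(len(cohort))
    if simple:
        batch = encode_cohort(cohort[simple], L, vocab, rng=None)
        b, _ = net.survival_scores(batch)
        beta[simple] = b.data
    for i in long_recs:
        scores = []
        for s in range(INFERENCE_SAMPLES):
            rng = np.random.default_rng(1_000_003 * s + 17)
            tok, val, pm = sample_and_pad(cohort.records[i], L, vocab, rng)
            b, _ = net.survival_scores(EncodedBatch(tok[None], val[None], pm[None]))
            scores.append(float(b.data[0]))
        beta[i] = float(np.mean(scores))
    return beta


# ----------------------------------------------------------------------
# risk stratification

def stratify_quartiles(beta_train: np.ndarray, beta_eval: np.ndarray,
                       n_groups: int = 4) -> np.ndarray:
    """Label patients Q1..Qn by training-score quantile cutoffs.

    Q1 = lowest scores (predicted short-term survivors). With
    ``n_groups=2`` this is the median high/low stratification.
    """
    beta_train = np.asarray(beta_train, dtype=float)
    if beta_train.size == 0:
        raise ValueError("training scores are empty")
    if np.allclose(beta_train, beta_train[0]):
        warnings.warn("degenerate (constant) training scores: single group")
        return np.array(["Q1"] * len(beta_eval))
    qs = np.percentile(beta_train, np.linspace(0, 100, n_groups + 1)[1:-1])
    labels = np.digitize(beta_eval, qs, right=False)
    return np.array([f"Q{i + 1}" for i in labels])
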