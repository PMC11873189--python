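"""Model/results surface: build a survival transformer from a cohort,
fit it under a training plan, and interrogate the fit.

:class:`TransformerSurvival` is constructed from a :class:`Cohort` (or a
pandas DataFrame via :meth:`TransformerSurvival.from_dataframe`); its
:meth:`fit` executes the configured learning strategy — direct survival
training, gradual learning (masked pretraining on the same cohort) or
transfer learning (pretraining on an external cohort) — across repeated
80/20 train/test splits and returns a
:class:`TransformerSurvivalResults` carrying the fitted per-split
networks, learning curves and test concordances. Explainability and
perturbation analyses hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import explain as _explain
from . import perturb as _perturb
from .cohort import (Cohort, Schema, Vocabulary, cohort_from_dataframe,
                     compute_max_length)
from .layers import ModelConfig
from .network import SurvivalTransformerNet
from .training import (FitHistory, TrainPlan, fine_tune, make_splits,
                       predict_scores, pretrain, stratify_quartiles)

__all__ = ["TransformerSurvival", "TransformerSurvivalResults"]


class TransformerSurvival:
    """Survival transformer model bound to a cohort.

    Parameters
    ----------
    cohort:
        Training/evaluation cohort (categoricals already ordinal-encoded).
    config:
        Architecture hyperparameters; ``vocab_size`` and ``max_len`` are
        filled in from the cohort.
    plan:
        Learning strategy, split layout and optimization settings.
    pretrain_cohort:
        External cohort for the ``transfer`` strategy (must be feature-
        compatible); ignored otherwise.
    max_len_percentile:
        Percentile of the per-patient feature-count distribution that
        sets the input length.
    """

    def __init__(self, cohort: Cohort, config: ModelConfig | None = None,
                 plan: TrainPlan | None = None,
                 pretrain_cohort: Cohort | None = None,
                 max_len_percentile: float = 95.0):
        self.cohort = cohort
        self.config = config if config is not None else ModelConfig()
        self.plan = plan if plan is not None else TrainPlan()
        self.pretrain_cohort = pretrain_cohort
        if self.plan.strategy == "transfer" and pretrain_cohort is None:
            raise ValueError("transfer learning requires a pretrain_cohort")
        if self.plan.strategy == "gradual" and pretrain_cohort is not None:
            raise ValueError("gradual learning pretrains on the same cohort; "
                             "do not pass pretrain_cohort")
        vocab_source = cohort if pretrain_cohort is None else Cohort(
            list(pretrain_cohort.records) + list(cohort.records))
        self.vocab = Vocabulary.from_cohort(vocab_source)
        self.config.vocab_size = len(self.vocab)
        if self.config.max_len == 0:
            self.config.max_len = compute_max_length(cohort, max_len_percentile)
        self.L = self.config.max_len

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       event_col: str = "event", id_col: str = "patient_id",
                       feature_types: dict[str, str] | None = None,
                       standardize: bool = False,
                       **kwargs) -> "TransformerSurvival":
        """Build from a wide table (one row per patient, NaN = missing)."""
        if feature_types is None:
            feature_types = {c: "continuous" for c in df.columns
                             if c not in (time_col, event_col, id_col)}
        schema = Schema(id_col=id_col, time_col=time_col, event_col=event_col,
                        feature_types=feature_types, standardize=standardize)
        cohort = cohort_from_dataframe(df, schema, fit=True)
        model = cls(cohort, **kwargs)
        model.schema = schema
        return model

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None,
            verbose: bool = False) -> "TransformerSurvivalResults":
        """Run the training plan and return the fitted results."""
        plan = self.plan
        seed = plan.seed if seed is None else seed
        splits = make_splits(len(self.cohort), plan.n_splits,
                             plan.train_frac, seed)
        base_net: SurvivalTransformerNet | None = None
        pretrain_log: list[dict] = []
        if plan.strategy in ("gradual", "transfer"):
            source = (self.cohort if plan.strategy == "gradual"
                      else self.pretrain_cohort)
            base_net, pretrain_log = pretrain(
                source, self.config, self.vocab, self.L,
                iters=plan.pretrain_iters, batch_size=plan.batch_size,
                lr=plan.lr, seed=seed, log_every=100)
        nets, histories = [], []
        for s, (train_idx, test_idx) in enumerate(splits):
            net = SurvivalTransformerNet(self.config, self.vocab,
                                         seed=seed + 101 * s)
            if base_net is not None:
                # warm-start the encoder; task heads stay freshly initialized
                net.copy_weights_from(base_net, encoder_only=True)
            hist = fine_tune(net, self.cohort, train_idx, test_idx, self.L,
                             epochs=plan.finetune_epochs,
                             batch_size=plan.batch_size, lr=plan.lr,
                             seed=seed + 101 * s, eval_every=plan.eval_every)
            if verbose and hist.test_c_index:
                print(f"split {s}: test C-index {hist.test_c_index[-1]:.3f}")
            nets.append(net)
            histories.append(hist)
        return TransformerSurvivalResults(self, splits, nets, histories,
                                          pretrain_log)


class TransformerSurvivalResults:
    """Fitted survival transformer: per-split networks and diagnostics.

    Attributes
    ----------
    splits : list of (train_idx, test_idx)
    networks : list of fitted :class:`SurvivalTransformerNet`, one per split
    histories : list of :class:`FitHistory` learning curves
    test_c_index_ : per-split final test C-index
    """

    def __init__(self, model: TransformerSurvival, splits, networks,
                 histories: list[FitHistory], pretrain_log=None):
        self.model = model
        self.splits = splits
        self.networks = networks
        self.histories = histories
        self.pretrain_log = pretrain_log or []
        self.test_c_index_ = np.array(
            [h.test_c_index[-1] if h.test_c_index else np.nan
             for h in histories])

    # -- prediction ------------------------------------------------------
    def predict(self, cohort: Cohort | None = None,
                split: int | None = None) -> np.ndarray:
        """Survival scores beta (higher = longer predicted survival).

        With ``split=None`` the scores are averaged over the per-split
        networks; otherwise a single split model is used.
        """
        cohort = self.model.cohort if cohort is None else cohort
        nets = self.networks if split is None else [self.networks[split]]
        return np.mean([predict_scores(net, cohort, self.model.L)
                        for net in nets], axis=0)

    def stratify(self, cohort: Cohort | None = None, n_groups: int = 4,
                 split: int = 0) -> np.ndarray:
        """Quantile risk groups from one split's training-score cutoffs."""
        cohort = self.model.cohort if cohort is None else cohort
        train_idx, _ = self.splits[split]
        beta_train = predict_scores(self.networks[split],
                                    self.model.cohort[list(train_idx)],
                                    self.model.L)
        beta_eval = predict_scores(self.networks[split], cohort, self.model.L)
        return stratify_quartiles(beta_train, beta_eval, n_groups=n_groups)

    # -- summaries -------------------------------------------------------
    def learning_curves(self) -> pd.DataFrame:
        rows = []
        for s, h in enumerate(self.histories):
            for e, ci, ls in zip(h.epochs, h.test_c_index, h.train_loss):
                rows.append({"split": s, "epoch": e, "test_c_index": ci,
                             "train_loss": ls})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Survival transformer fit",
                 "=" * 38,
                 f"patients:            {len(self.model.cohort)}",
                 f"features:            {self.model.vocab.n_features}",
                 f"input length L:      {self.model.L}",
                 f"strategy:            {self.model.plan.strategy}",
                 f"splits:              {len(self.splits)} "
                 f"({self.model.plan.train_frac:.0%} train)",
                 f"epochs per split:    {self.model.plan.finetune_epochs}",
                 "-" * 38]
        ci = self.test_c_index_
        ok = ci[~np.isnan(ci)]
        if len(ok):
            lines.append(f"test C-index:        {ok.mean():.3f} "
                         f"+/- {ok.std():.3f}")
            for s, c in enumerate(ci):
                lines.append(f"  split {s:2d}:          {c:.3f}")
        return "\n".join(lines)

    # -- explainability ---------------------------------------------------
    def permutation_importance(self, n_repeats: int = 10,
                               seed: int = 0) -> pd.DataFrame:
        """Mean C-index drop per feature over the test splits.

        Runs the shuffle test on each split's test cohort with that
        split's network; returns features x (split, repeat) drops.
        """
        frames = []
        for s, (train_idx, test_idx) in enumerate(self.splits):
            if len(test_idx) == 0:
                continue
            rng = np.random.default_rng(seed + s)
            df = _explain.permutation_importance(
                self.networks[s], self.model.cohort[list(test_idx)],
                self.model.L, n_repeats=n_repeats, rng=rng)
            df.columns = pd.MultiIndex.from_product([[s], df.columns])
            frames.append(df)
        return pd.concat(frames, axis=1)

    def interaction_matrix(self, split: int = 0,
                           patient_ids=None) -> _explain.InteractionMatrix:
        return _explain.interaction_matrix(
            self.networks[split], self.model.cohort, self.model.L,
            patient_ids=patient_ids)

    def functional_groups(self, split: int = 0, n_groups: int | None = None,
                          method: str = "agglomerative",
                          ) -> list[_explain.FunctionalGroup]:
        im = self.interaction_matrix(split=split)
        return _explain.cluster_functional_groups(im, n_groups=n_groups,
                                                  method=method)

    # -- perturbation ------------------------------------------------------
    def perturb_single(self, feature: str, split: int = 0,
                       cohort: Cohort | None = None,
                       n_grid: int = 10) -> _perturb.PerturbationGrid:
        cohort = self.model.cohort if cohort is None else cohort
        train_idx, _ = self.splits[split]
        return _perturb.perturb_single(
            self.networks[split], cohort, feature, self.model.L,
            train_cohort=self.model.cohort[list(train_idx)], n_grid=n_grid)

    def perturb_pair(self, pair: tuple[str, str], split: int = 0,
                     cohort: Cohort | None = None, n_repeats: int = 50,
                     seed: int = 0) -> _perturb.PerturbationGrid:
        cohort = self.model.cohort if cohort is None else cohort
        train_idx, _ = self.splits[split]
        return _perturb.perturb_pair(
            self.networks[split], cohort, pair, self.model.L,
            train_cohort=self.model.cohort[list(train_idx)],
            n_repeats=n_repeats, rng=np.random.default_rng(seed))

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        for s, net in enumerate(self.networks):
            net.save(d / f"split_{s:02d}")
        self.learning_curves().to_csv(d / "learning_curves.csv", index=False)
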