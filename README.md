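# survformer

A permutation-invariant transformer for survival prediction on tabular
clinicogenomic data — with masked-feature self-supervised pretraining,
embedding-based explainability, and a generative in-silico perturbation
engine.

## The problem

Clinical and translational oncology datasets are small (hundreds to a
few thousand patients), sparse (rare mutation calls), multimodal
(laboratory values, demographics, genomics) and riddled with
missingness; the outcome of interest is a right-censored survival time.
`survformer` treats each patient as a *set* of (feature-name, value)
pairs — missing measurements are simply absent, never imputed — and
feeds them to a transformer encoder **without positional encoding**, so
predictions are provably invariant to feature order. A special TASK
token aggregates the patient representation; a single bias-free linear
neuron on its output embedding yields the survival score
beta = P_task · W^T (higher = longer predicted survival).

Training maximizes concordance directly through a differentiable
sigmoid surrogate of Harrell's C-index,

```
L = Σ_{i,j} w_ij · 1 / (1 + exp((β_j − β_i)/σ)),
w_ij = Δ_i · I(T_i < T_j) / Σ Δ_i · I(T_i < T_j),
```

summed over comparable pairs (patient i died and T_i < T_j) within each
mini-batch. Because labels are expensive, the encoder can first be
pretrained by masked-feature self-supervision — 20% of feature *names*
replaced by a MASK token and reconstructed from the rest
(loss = 1·cross-entropy + 0.01·MSE) — either on the same cohort
("gradual learning") or on a larger external one ("transfer learning").

A fitted model is interrogated three ways:

* **Permutation importance** — drop in test C-index when one feature's
  observed values are shuffled across patients.
* **Functional groups** — pairwise cosine similarity between last-layer
  output embeddings, averaged over a population, clustered into groups
  of features that carry redundant outcome-relevant information; groups
  of mutation features are binarized (any member mutated) and distilled
  into an interpretable Cox proportional-hazards model.
* **Perturbation analysis** — sweep one or two features over their
  training distribution while holding the rest fixed; the spread
  Δβ = max − min of perturbed scores separates a *variant* (sensitive)
  from an *invariant* population at the median, and
  Diff = max(−log p(f), −log p(g)) − (−log p(f,g)) from rank-sum tests
  flags pairs whose joint perturbation outranks both marginals.

A built-in simulator generates cohorts with known log-hazards
(correlated feature blocks, sparse mutations, interactions, calibrated
censoring), so every claim is testable against ground truth. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from survformer import (ModelConfig, SimSpec, TrainPlan,
                        TransformerSurvival, simulate_cohort)

cohort, truth = simulate_cohort(SimSpec(seed=7))   # 600 patients,
# 12 features (4 informative, log-hazard SD 1), 30% censoring

model = TransformerSurvival(
    cohort,
    config=ModelConfig(d_k=64, n_layers=2, n_heads=4),
    plan=TrainPlan(strategy="direct", n_splits=10, finetune_epochs=30))
res = model.fit(seed=0)
print(res.summary())
```

```
Survival transformer fit
======================================
patients:            600
features:            12
input length L:      13
strategy:            direct
splits:              10 (80% train)
epochs per split:    30
--------------------------------------
test C-index:        0.707 +/- 0.030
  split  0:          0.705
  split  1:          0.700
  split  2:          0.709
  split  3:          0.695
  split  4:          0.717
  split  5:          0.670
  split  6:          0.758
  split  7:          0.659
  split  8:          0.750
  split  9:          0.710
```

A mean test C-index around 0.71 against a ground-truth oracle of ≈ 0.72
(the concordance of the true log-hazard itself, the ceiling any model
can reach on this draw) means the encoder has recovered most of the
planted signal. Downstream:

```python
imp = res.permutation_importance(n_repeats=10)   # f1..f4 rank on top
groups = res.functional_groups(n_groups=3)       # cosine clusters
grid = res.perturb_single("f1")                  # counterfactual sweep
```

The same pipeline is scriptable from the shell
(`survformer simulate | pretrain | train | predict | explain | perturb |
report`), driven by one YAML config; every run writes a resolved-config
copy and a seed manifest next to its outputs.

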