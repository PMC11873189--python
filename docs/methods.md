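# Methods

## The model

`survformer` fits a transformer encoder to tabular clinicogenomic
cohorts for right-censored survival prediction. A patient is a *set* of
(feature-name, value) pairs — continuous laboratory values, ordinal-coded
categoricals, sparse binary mutation flags — plus a survival time in
months and an event indicator (1 = death observed, 0 = censored).
Missing measurements are simply absent from the set; there are no
sentinel values and no imputation.

Each observed feature is embedded as the sum of a learned name embedding
(a token lookup) and a linear projection of its scalar value into the
same d_k-dimensional space. A special `[TASK, 1]` token is prepended to
every input; absent slots are `[PAD]` and are masked out of attention
and all losses. The encoder is a standard post-norm transformer stack
(multi-head scaled dot-product attention, residual + layer norm,
position-wise feed-forward, residual + layer norm) with **no positional
encoding**: a patient's features have no natural order, and omitting the
positional term makes the survival score provably invariant to feature
order (verified to <1e-5 on trained models; exact up to floating-point
associativity). The survival head is a single bias-free linear neuron on
the TASK output embedding, so the score is beta = P_task · W^T, with
higher beta meaning longer predicted survival.

### Survival objective

Training minimizes a smooth surrogate of Harrell's concordance index,

    L = sum_{i,j} w_ij / (1 + exp((beta_j - beta_i) / sigma)),
    w_ij = Delta_i I(T_i < T_j) / sum_{i,j} Delta_i I(T_i < T_j),

summed over comparable pairs within each mini-batch (pairs with tied
times are non-comparable; the normalizer is only computable per batch).
The loss lies in (0, 1), equals 0.5 exactly when all scores tie, and
approaches 1 − C-index as sigma → 0 on tie-free data. The smoothing
parameter defaults to sigma = 0.1: large sigma gives smoother gradients
but a looser approximation to the step function; the unit suite sweeps
{1, 0.1, 0.01} against a brute-force pair enumeration. Evaluation uses
the exact Harrell C-index with half credit for tied scores.

### Masked pretraining

Self-supervision hides 20% of a row's feature *names* (ceil of the
fraction, at least one; the values stay visible, TASK/PAD are never
masked) and reconstructs them with two heads on the masked output
embeddings: a softmax over the feature-name vocabulary (categorical
cross-entropy) and a linear scalar head (mean squared error). The total
loss is alpha_names * CE + alpha_values * MSE with alpha_names = 1 and
alpha_values = 0.01, averaged per masked slot (stable under variable
mask counts); names dominate because the masked values remain visible
inputs. Three strategies use this: *direct* (no pretraining), *gradual*
(pretrain and fine-tune on the same cohort) and *transfer* (pretrain on
an external cohort sharing the vocabulary). Fine-tuning warm-starts the
encoder only; the survival head is always freshly initialized.

### Input-length policy

The row length L is 1 + the 95th percentile (linear interpolation,
rounded up) of the per-patient non-missing feature count, capped at
1 + the number of unique features. During training, records longer than
L−1 are subsampled uniformly without replacement, fresh each iteration.
At inference the policy is deterministic: records that fit are encoded
once with all features in vocabulary order; longer records are scored as
the mean over 20 fixed-seed subsamples, which removes prediction
nondeterminism at the cost of a small Monte-Carlo error.

## Numerical and optimization choices

The network runs on a small reverse-mode autodiff engine over float64
numpy arrays — CPU-friendly, bitwise reproducible, and gradient-checked
against central finite differences in the test suite. Defaults: d_k=128,
4 layers, 4 heads, feed-forward width 4·d_k, dropout 0.1, truncated-
normal (std 0.02) initialization with a fixed seed; Adam with learning
rate 1e-3, batch size 64, global-norm gradient clipping at 1.0. The
learning rate is deliberately higher than the 1e-4 typical of large
pretrained encoders: at cohort scale (hundreds of patients, tens of
features) a few thousand optimizer steps must suffice, and 1e-3 uses
the epoch budget efficiently while remaining stable under clipping.
Continuous features can be z-scored with training-split statistics
stored in the schema (the value projection is linear, so scaling
stabilizes optimization); binary and ordinal features pass through raw.
Categoricals with n levels are coded as ordinals 0..n−1 (information-
preserving); codebooks are fitted on training data, serialized with the
model, and unseen categories at inference map to a reserved ordinal with
a warning. Attention logits on PAD columns are set to −1e9 before the
softmax; each row is checked to sum to 1 over non-PAD columns within
1e-5. NaN activations abort with the offending layer index.

Evaluation uses repeated stratification-free random 80/20 train/test
splits (10 by default), serialized to JSON for exact reuse, with a
per-epoch test C-index learning curve per split. There is no early
stopping; a fixed epoch budget with curve logging keeps the comparison
between strategies transparent.

## Explainability

Interactions are read out of the *output* embeddings of the last
encoder layer (they sit immediately before the prediction heads and
aggregate the whole network's nonlinearity, unlike raw attention
weights, which are deliberately not used for attribution). For each
patient, cosine similarities are computed between all observed-feature
embeddings and against the TASK embedding; population matrices average
the per-patient cosines over the patients where both features are
observed (never co-observed pairs are flagged missing and imputed with
value 1 before clustering, treating unknown pairs as maximally
redundant so they cannot spuriously separate). Functional groups come
from agglomerative clustering (average linkage on 1 − cosine; k-means on
the similarity rows is available) with the silhouette score selecting
the group count when unspecified. Groups are ranked per subpopulation
(e.g. survival quartiles) by mean within-group cosine: groups high
everywhere are "core", groups enriched in one subpopulation are
"targets".

Permutation feature importance shuffles one feature's observed values
across the patients that carry it (preserving the missingness pattern)
and reports the drop in test C-index, 10 repeats per feature per split
model.

Mutation-derived groups are binarized per patient (1 iff any member gene
mutated) and validated with univariate Cox proportional-hazards fits
(lifelines, Efron ties, Wald tests); groups at raw p < 0.05 are kept and
ranked by hazard ratio, with Benjamini-Hochberg-adjusted p-values
reported alongside for transparency. The top groups feed a multivariate
Cox model — a distillation of the transformer into an interpretable
linear model — evaluated by test-split C-index and median-training-risk
stratification, with same-size random gene groups as the control.

## Perturbation analysis

The trained network scores counterfactual inputs. Single-feature
perturbation sweeps a feature over the midpoints of the 10 deciles of
its training distribution (5th, 15th, ..., 95th percentile values;
observed ordinal codes for categoricals, unique values when fewer than
10 exist), holding all other features exactly at their observed values.
Pairwise perturbation draws the (f, g) value pair jointly from a random
training patient carrying both — preserving their empirical joint
distribution — 50 times per patient. Per patient, Delta-beta =
max − min of the perturbed scores measures sensitivity; the per-patient
*maximum* perturbed score M_p enters a two-sided Mann-Whitney test
against the unperturbed score distribution of the same (filtered)
population. Significance is combined as

    Diff = max(−log10 p(f), −log10 p(g)) − (−log10 p(f, g)),

negative when the joint perturbation is more significant than either
marginal (an interaction; the sign logic is base-invariant, base 10 is
convention). The median split of Delta-beta — by default restricted to
the poor and low-mid survivors (training quartiles Q1 and Q2) — defines
the variant (sensitive) and invariant populations, with stable-order tie
breaking so group sizes differ by at most one; variant patients whose
best perturbed score crosses the training Q1 cutoff are reported as
perturbation-rescued. Population contrasts use two-sided Welch t-tests
with Bonferroni correction; binary features are summarized as
proportions.

## The synthetic cohort generator

Every statistical claim in the test suite runs against simulated
cohorts with known ground truth. The generator emulates the structure of
tabular clinical-trial data: compound-symmetric Gaussian blocks of
continuous covariates (within-block correlation rho), Bernoulli mutation
flags with configurable prevalence, missing-completely-at-random cell
deletion applied after outcome generation, and survival times from the
proportional-hazards inverse transform T = H0^{-1}(−log U / exp(eta))
with exponential (default, median 12 months under the null) or Weibull
baseline. The log-hazard eta combines linear main effects, optional
product interactions and any-gene-mutated group effects; −eta is the
ground-truth survival score, and its concordance on the drawn cohort is
the oracle that upper-bounds what any model can reach. Censoring is an
independent exponential whose rate is root-solved against the realized
event times so the achieved censoring fraction matches the target
(within ±0.03 at n = 2000).

The default conditions — 600 patients, 12 independent standard-normal
features of which 4 carry coefficients ±0.5 (linear predictor SD 1,
oracle concordance ≈ 0.72–0.78), 30% censoring — define the standard
signal-recovery experiment; a 300-patient version backs the
pretraining-benefit comparison, and a 3-block rho = 0.8 version backs
functional-group recovery. A co-occurrence generator (features strictly
co-present by rule) gives masked-name prediction a known attainable
accuracy for pretraining tests. The cross-block interaction property —
pairs spanning the two blocks should dominate the most-negative-Diff
ranking when the log-hazard's only interaction is a scaled product of
the two block sums — is tested with counts pooled over five fixed-seed
cohorts, because a single 15-pair draw cannot reach the 0.05 level even
when every top pair is cross-block.

What the simulations do *not* emulate: informative missingness,
non-proportional hazards, calendar-time effects, batch effects, mixed
assay scales, and the heavy-tailed marginals of real laboratory values.
Passing these tests therefore demonstrates correctness of the machinery
and recoverability of planted structure at realistic sizes — not
clinical performance on any real cohort.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run, by design, at desk scale:
training cohorts of 150–600 patients, 2 encoder layers, d_k = 32–64,
10–30 epochs, 10 splits; pretraining 1500–2000 iterations; 7 paired
seeds for the direct-vs-gradual comparison; 200 replicates for Wald CI
coverage. These sizes were chosen so the full pipeline exercises every
component end-to-end on a single CPU while keeping Monte-Carlo error
small relative to the tested margins.

## Known limitations

- The C-index surrogate enumerates pairs within mini-batches only;
  batches without a comparable pair are skipped with a warning.
- Value reconstruction during pretraining is partially self-revealing
  (masked values stay visible), which is why it is down-weighted.
- Cosine-based groups are population averages; per-patient interaction
  structure is available but not clustered.
- The ordinal coding of categoricals imposes an artificial order on the
  value-projection axis; with many unordered levels, one-hot expansion
  into binary features is the better encoding.
- CPU-only: the engine is intended for cohorts up to a few thousand
  patients and a few hundred observed features per patient.
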