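"""Explainability: permutation importance, embedding cosine interactions,
functional groups, and Cox-model simplification.

Feature interactions are read out of the *output* embeddings of the last
encoder layer ("post-attention"): for each patient, the cosine similarity
between every pair of observed-feature embeddings, and between each
feature embedding and the outcome (TASK) embedding, averaged over a
population. High cosine = redundant information, near zero = orthogonal,
negative = inverse relationship. Clustering the mean similarity matrix
yields functional groups — sets of features carrying related
outcome-relevant information — which can be binarized (any member
mutated) and distilled into an interpretable Cox proportional-hazards
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from .cohort import Cohort, PatientRecord, Vocabulary, encode_cohort
from .losses import NoComparablePairs, c_index
from .network import SurvivalTransformerNet
from .survstats import CoxSummary, cox_fit, hazard_ratio
from .training import predict_scores

__all__ = [
    "InteractionMatrix", "FunctionalGroup", "permutation_importance",
    "cosine_similarity", "interaction_matrix", "cluster_functional_groups",
    "rank_functional_groups", "binarize_group", "validate_groups_cox",
    "simplify_to_cox",
]


# ----------------------------------------------------------------------
# permutation feature importance

def permutation_importance(net: SurvivalTransformerNet, cohort: Cohort,
                           L: int, n_repeats: int = 10,
                           rng: np.random.Generator | None = None,
                           features: list[str] | None = None) -> pd.DataFrame:
    """Drop in test C-index when one feature's values are shuffled.

    The feature's observed values are permuted across the patients that
    carry it (the missingness pattern is preserved); importance =
    baseline C-index - permuted C-index, one column per repeat.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    features = cohort.feature_names if features is None else features
    baseline = c_index(predict_scores(net, cohort, L),
                       cohort.times, cohort.events)
    rows = {}
    for name in features:
        holders = [i for i, r in enumerate(cohort) if name in r.features]
        if len(holders) == 0:
            rows[name] = np.zeros(n_repeats)
            continue
        if len(holders) < 2:
            warnings.warn(f"feature {name!r} observed in <2 patients; skipped")
            continue
        vals = np.array([cohort.records[i].features[name] for i in holders])
        drops = []
        for _ in range(n_repeats):
            shuffled = vals[rng.permutation(len(vals))]
            perturbed = []
            pos = {i: k for k, i in enumerate(holders)}
            for i, r in enumerate(cohort):
                feats = dict(r.features)
                if i in pos:
                    feats[name] = float(shuffled[pos[i]])
                perturbed.append(PatientRecord(r.patient_id, feats,
                                               r.time, r.event))
            pc = Cohort(perturbed)
            try:
                ci = c_index(predict_scores(net, pc, L), pc.times, pc.events)
            except NoComparablePairs:
                continue
            drops.append(baseline - ci)
        rows[name] = np.array(drops)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature"
    return df


# ----------------------------------------------------------------------
# cosine interactions

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a||b|); undefined for a zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


@dataclass
class InteractionMatrix:
    """Population-mean pairwise cosine similarities between features.

    ``S[i, j]`` is the mean cosine over patients where features i and j
    are both observed (NaN when never co-observed); ``outcome[i]`` is the
    mean cosine between feature i's embedding and the outcome (TASK)
    embedding; ``coverage`` counts contributing patients per pair.
    """

    features: list[str]
    S: np.ndarray
    coverage: np.ndarray
    outcome: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.features, columns=self.features)


def interaction_matrix(net: SurvivalTransformerNet, cohort: Cohort,
                       L: int, patient_ids: list[str] | None = None
                       ) -> InteractionMatrix:
    """Mean post-attention cosine matrix over a population.

    Per patient, the last-layer output embeddings of all observed
    features (PAD excluded) are compared pairwise and against the TASK
    embedding; per-pair means are taken over the patients where both
    features are present, as population averages of per-patient cosines.
    """
    if patient_ids is not None:
        keep = set(patient_ids)
        cohort = Cohort([r for r in cohort if r.patient_id in keep])
    features = net.vocab.feature_names
    fidx = {name: i for i, name in enumerate(features)}
    F = len(features)
    sums = np.zeros((F, F))
    counts = np.zeros((F, F), dtype=int)
    out_sums = np.zeros(F)
    out_counts = np.zeros(F, dtype=int)
    batch = encode_cohort(cohort, L, net.vocab, rng=None)
    _, eset = net.forward(batch)
    for b in range(len(cohort)):
        slots = np.flatnonzero(~batch.pad_mask[b])
        feat_slots = slots[batch.token_ids[b, slots] >= Vocabulary.N_RESERVED]
        if len(feat_slots) == 0:
            continue
        emb = eset.P[b, feat_slots]                     # (k, d)
        norms = np.linalg.norm(emb, axis=1)
        norms[norms == 0] = 1.0
        unit = emb / norms[:, None]
        cos = unit @ unit.T
        task = eset.P[b, 0]
        tn = np.linalg.norm(task)
        cos_task = unit @ (task / tn if tn > 0 else task)
        ids = [fidx[net.vocab.name_of(t)] for t in batch.token_ids[b, feat_slots]]
        ids = np.asarray(ids)
        sums[np.ix_(ids, ids)] += cos
        counts[np.ix_(ids, ids)] += 1
        out_sums[ids] += cos_task
        out_counts[ids] += 1
    with np.errstate(invalid="ignore"):
        S = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        outcome = np.where(out_counts > 0,
                           out_sums / np.maximum(out_counts, 1), np.nan)
    return InteractionMatrix(features=features, S=S, coverage=counts,
                             outcome=outcome)


# ----------------------------------------------------------------------
# functional groups

@dataclass
class FunctionalGroup:
    """A cluster of features sharing outcome-relevant information."""

    id: str
    members: list[str]
    mean_within_cosine: float


def _impute(S: np.ndarray) -> np.ndarray:
    """Missing (never co-observed) pairs are encoded with value 1."""
    out = S.copy()
    out[np.isnan(out)] = 1.0
    np.fill_diagonal(out, 1.0)
    return out


def _mean_within(S: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) < 2:
        return 1.0
    sub = S[np.ix_(idx, idx)]
    off = sub[~np.eye(len(idx), dtype=bool)]
    off = off[~np.isnan(off)]
    return float(off.mean()) if len(off) else float("nan")


def cluster_functional_groups(im: InteractionMatrix,
                              n_groups: int | None = None,
                              method: str = "agglomerative",
                              random_state: int = 0
                              ) -> list[FunctionalGroup]:
    """Partition features into functional groups on the cosine matrix.

    Distance is 1 - cosine; agglomerative clustering uses average linkage
    on the precomputed distances, k-means runs on the rows of the
    (imputed) similarity matrix. When ``n_groups`` is None the silhouette
    score selects it from 2..min(F-1, 10).
    """
    F = len(im.features)
    if n_groups is not None and n_groups > F:
        raise ValueError("more groups requested than features")
    S = _impute(im.S)
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2

    def labels_for(k: int) -> np.ndarray:
        if k >= F:
            return np.arange(F)
        if method == "agglomerative":
            model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                            linkage="average")
            return model.fit_predict(D)
        if method == "kmeans":
            model = KMeans(n_clusters=k, n_init=10, random_state=random_state)
            return model.fit_predict(S)
        raise ValueError(f"unknown clustering method {method!r}")

    if n_groups is None:
        best_k, best_score = 2, -np.inf
        for k in range(2, min(F - 1, 10) + 1):
            lab = labels_for(k)
            if len(set(lab)) < 2:
                continue
            score = silhouette_score(D, lab, metric="precomputed")
            if score > best_score:
                best_k, best_score = k, score
        n_groups = best_k
    labels = labels_for(n_groups)
    groups = []
    for k in sorted(set(labels)):
        idx = np.flatnonzero(labels == k)
        members = [im.features[i] for i in idx]
        groups.append(FunctionalGroup(id=f"C{k + 1}", members=members,
                                      mean_within_cosine=_mean_within(im.S, idx)))
    return groups


def rank_functional_groups(groups: list[FunctionalGroup],
                           matrices: dict[str, InteractionMatrix]
                           ) -> pd.DataFrame:
    """Rank groups per subpopulation by mean within-group cosine.

    ``matrices`` maps subpopulation label -> that subpopulation's
    interaction matrix. The returned tidy table carries, per group and
    subpopulation, the mean within-group cosine, the mean group-to-
    outcome cosine, and the within-subpopulation rank (1 = highest
    cosine). Groups ranking high everywhere are "core"; groups enriched
    in specific subpopulations are "target" groups.
    """
    rows = []
    for pop, im in matrices.items():
        fidx = {name: i for i, name in enumerate(im.features)}
        for g in groups:
            idx = np.asarray([fidx[m] for m in g.members if m in fidx])
            within = _mean_within(im.S, idx)
            out = im.outcome[idx]
            out = out[~np.isnan(out)]
            rows.append({"group": g.id, "subpopulation": pop,
                         "mean_within_cosine": within,
                         "mean_outcome_cosine": float(out.mean()) if len(out)
                         else float("nan")})
    df = pd.DataFrame(rows)
    df["rank"] = df.groupby("subpopulation")["mean_within_cosine"] \
                   .rank(ascending=False, method="min").astype(int)
    return df.sort_values(["subpopulation", "rank"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# binarization and Cox distillation

def binarize_group(members: list[str], mutations: pd.DataFrame) -> np.ndarray:
    """Any-member-mutated indicator per patient.

    ``mutations`` is a patients x genes 0/1 table; the group indicator is
    1 iff at least one member gene is mutated.
    """
    cols = [m for m in members if m in mutations.columns]
    if not cols:
        raise ValueError("no group member present in the mutation table")
    sub = mutations[cols].to_numpy(dtype=float)
    vals = sub[~np.isnan(sub)]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("binarize_group requires binary (0/1) member features")
    return (np.nansum(sub, axis=1) > 0).astype(int)


def validate_groups_cox(indicators: pd.DataFrame, T, delta,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Univariate Cox PH per binarized group; keep Wald p < alpha.

    Returns a table (one row per fitted group) with coef, HR, CI, raw and
    Benjamini-Hochberg-adjusted p, flagged significance, ranked by HR
    (most protective first). Degenerate indicators are skipped with a
    warning.
    """
    rows = {}
    for gid in indicators.columns:
        x = indicators[gid].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            warnings.warn(f"group {gid}: constant indicator, skipped")
            continue
        try:
            summ = hazard_ratio(x, T, delta)
        except Exception as exc:  # separation / convergence failure
            warnings.warn(f"group {gid}: Cox fit failed ({exc}); skipped")
            continue
        rows[gid] = summ.table.loc["group"]
    if not rows:
        return pd.DataFrame(columns=["coef", "hazard_ratio", "ci_lower",
                                     "ci_upper", "p", "p_bh", "significant"])
    df = pd.DataFrame(rows).T
    df.index.name = "group"
    # Benjamini-Hochberg, reported for transparency (selection uses raw p)
    p = df["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    bh = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * m / (rank_i + 1))
        bh[i] = running
    df["p_bh"] = bh
    df["significant"] = df["p"] < alpha
    return df.sort_values("hazard_ratio")


def simplify_to_cox(indicators: pd.DataFrame, T, delta,
                    splits: list[tuple[np.ndarray, np.ndarray]],
                    penalizer: float = 0.0) -> dict:
    """Distill selected groups into a multivariate Cox PH model.

    Fits one multivariate Cox model per train split on the binary group
    indicators, evaluates the C-index on the matching test split, and
    stratifies test patients into high/low risk at the median training
    partial-hazard score. Collinear designs are retried with a ridge
    penalty. Returns per-split C-indexes, stratification labels, and a
    full-data :class:`CoxSummary`.
    """
    if indicators.shape[1] == 0:
        raise ValueError("no groups supplied to simplify_to_cox")
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    df = indicators.copy()
    df["time"] = T
    df["event"] = delta

    def fit(frame: pd.DataFrame) -> CoxSummary:
        try:
            return cox_fit(frame, penalizer=penalizer)
        except Exception:
            warnings.warn("collinear indicators: refitting with ridge penalty")
            return cox_fit(frame, penalizer=0.1)

    test_c, labels = [], []
    for train_idx, test_idx in splits:
        summ = fit(df.iloc[train_idx])
        coefs = summ.table["coef"].reindex(indicators.columns).fillna(0.0)
        risk_train = indicators.iloc[train_idx].to_numpy() @ coefs.to_numpy()
        risk_test = indicators.iloc[test_idx].to_numpy() @ coefs.to_numpy()
        try:
            # risk is a hazard score: higher risk = shorter survival
            test_c.append(c_index(-risk_test, T[test_idx], delta[test_idx]))
        except NoComparablePairs:
            test_c.append(float("nan"))
        cutoff = float(np.median(risk_train))
        labels.append(np.where(risk_test > cutoff, "high", "low"))
    full = fit(df)
    return {"test_c_index": np.asarray(test_c), "risk_labels": labels,
            "full_fit": full}
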