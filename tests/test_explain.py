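"""Explainability: cosine arithmetic, interaction-matrix bookkeeping,
functional-group clustering, binarization and Cox distillation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from survformer import SimSpec, simulate_cohort
from survformer.explain import (InteractionMatrix, binarize_group,
                                cluster_functional_groups, cosine_similarity,
                                interaction_matrix, permutation_importance,
                                rank_functional_groups, simplify_to_cox,
                                validate_groups_cox)
from survformer.training import make_splits


class TestCosine:
    def test_identity_and_antipode(self, rng):
        v = rng.normal(size=8)
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_unit_vectors(self):
        assert cosine_similarity([1, 0, 0], [0, 1, 0]) == 0.0

    def test_explicit_arithmetic(self):
        got = cosine_similarity([1, 2, 3], [4, 5, 6])
        assert got == pytest.approx(32 / (np.sqrt(14) * np.sqrt(77)), rel=1e-12)

    def test_zero_vector_undefined(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestInteractionMatrix:
    def test_symmetry_unit_diagonal_and_range(self, small_fit):
        model, res, _ = small_fit
        im = res.interaction_matrix(split=0)
        obs = ~np.isnan(im.S)
        assert np.allclose(im.S[obs], im.S.T[obs], atol=1e-12)
        assert np.allclose(np.diag(im.S), 1.0, atol=1e-9)
        assert np.nanmax(im.S) <= 1 + 1e-9 and np.nanmin(im.S) >= -1 - 1e-9

    def test_single_patient_population_is_own_matrix(self, small_fit):
        model, res, _ = small_fit
        pid = model.cohort[0].patient_id
        im1 = res.interaction_matrix(split=0, patient_ids=[pid])
        assert (im1.coverage[~np.isnan(im1.S)] == 1).all()

    def test_never_coobserved_pair_flagged_missing(self, small_fit):
        model, res, _ = small_fit
        # restrict to a single patient: features absent there are missing
        r0 = model.cohort[0]
        im = res.interaction_matrix(split=0, patient_ids=[r0.patient_id])
        absent = [f for f in model.vocab.feature_names
                  if f not in r0.features]
        if absent:
            i = im.features.index(absent[0])
            assert np.isnan(im.S[i]).all() or np.isnan(im.S[i, i])


class TestClustering:
    def _block_matrix(self):
        S = np.full((6, 6), 0.05)
        S[:3, :3] = 0.95
        S[3:, 3:] = 0.95
        np.fill_diagonal(S, 1.0)
        return InteractionMatrix(features=[f"f{i}" for i in range(6)], S=S,
                                 coverage=np.full((6, 6), 10),
                                 outcome=np.zeros(6))

    @pytest.mark.parametrize("method", ["agglomerative", "kmeans"])
    def test_perfect_blocks_recovered(self, method):
        groups = cluster_functional_groups(self._block_matrix(), n_groups=2,
                                           method=method)
        parts = sorted(sorted(g.members) for g in groups)
        assert parts == [["f0", "f1", "f2"], ["f3", "f4", "f5"]]
        assert all(g.mean_within_cosine == pytest.approx(0.95) for g in groups)

    def test_auto_group_count_by_silhouette(self):
        groups = cluster_functional_groups(self._block_matrix(), n_groups=None)
        assert len(groups) == 2

    def test_singleton_boundary(self):
        groups = cluster_functional_groups(self._block_matrix(), n_groups=6)
        assert len(groups) == 6
        assert all(len(g.members) == 1 for g in groups)

    def test_too_many_groups_fatal(self):
        with pytest.raises(ValueError):
            cluster_functional_groups(self._block_matrix(), n_groups=7)

    def test_missing_pairs_imputed_with_one(self):
        im = self._block_matrix()
        im.S[0, 5] = im.S[5, 0] = np.nan
        groups = cluster_functional_groups(im, n_groups=2)
        assert len(groups) == 2  # imputation value 1 does not crash/merge all

    def test_deterministic_given_seed(self):
        a = cluster_functional_groups(self._block_matrix(), n_groups=2,
                                      method="kmeans", random_state=3)
        b = cluster_functional_groups(self._block_matrix(), n_groups=2,
                                      method="kmeans", random_state=3)
        assert [g.members for g in a] == [g.members for g in b]


class TestRanking:
    def _im(self, S):
        F = S.shape[0]
        return InteractionMatrix(features=[f"f{i}" for i in range(F)], S=S,
                                 coverage=np.full((F, F), 5),
                                 outcome=np.linspace(0, 1, F))

    def test_maximal_group_ranks_first_everywhere(self):
        S = np.full((4, 4), 0.2)
        S[:2, :2] = 1.0
        np.fill_diagonal(S, 1.0)
        from survformer.explain import FunctionalGroup
        groups = [FunctionalGroup("C1", ["f0", "f1"], 1.0),
                  FunctionalGroup("C2", ["f2", "f3"], 0.2)]
        table = rank_functional_groups(groups,
                                       {"Q1": self._im(S), "Q4": self._im(S)})
        top = table[table["rank"] == 1]
        assert set(top["group"]) == {"C1"}
        assert len(top) == 2   # rank 1 in both subpopulations: a core group

    def test_label_shuffle_removes_rank_differences(self, small_fit, rng):
        """Interaction matrices of random halves rank groups alike."""
        model, res, _ = small_fit
        ids = np.array(model.cohort.patient_ids)
        groups = res.functional_groups(split=0, n_groups=2)
        diffs = []
        for _ in range(5):
            half = rng.permutation(len(ids))[:len(ids) // 2]
            im_a = res.interaction_matrix(split=0, patient_ids=ids[half])
            im_b = res.interaction_matrix(
                split=0, patient_ids=np.delete(ids, half))
            t = rank_functional_groups(groups, {"A": im_a, "B": im_b})
            piv = t.pivot(index="group", columns="subpopulation",
                          values="mean_within_cosine")
            diffs.append(float((piv["A"] - piv["B"]).abs().mean()))
        assert np.mean(diffs) < 0.15


class TestBinarize:
    def test_zero_branch(self):
        muts = pd.DataFrame({"g1": [0, 0], "g2": [0, 1]})
        z = binarize_group(["g1", "g2"], muts)
        assert z.tolist() == [0, 1]

    def test_one_of_many_genes_suffices(self):
        muts = pd.DataFrame({f"g{i}": [0] * 3 for i in range(9)})
        muts.loc[1, "g7"] = 1
        z = binarize_group([f"g{i}" for i in range(9)], muts)
        assert z.tolist() == [0, 1, 0]

    def test_matches_rowwise_any_oracle(self, rng):
        muts = pd.DataFrame(rng.integers(0, 2, size=(5, 3)),
                            columns=["a", "b", "c"])
        z = binarize_group(["a", "b", "c"], muts)
        assert (z == muts.any(axis=1).astype(int).to_numpy()).all()

    def test_non_binary_member_fatal(self):
        muts = pd.DataFrame({"a": [0, 2.5]})
        with pytest.raises(ValueError, match="binary"):
            binarize_group(["a"], muts)


def _mutation_cohort(seed, n=400, protective=-0.7):
    spec = SimSpec(n_patients=n, block_sizes=(1,), n_mutations=6,
                   mutation_prevalence=0.25, coefficients={"f1": 0.3},
                   group_effects=[(["m1", "m2"], protective)],
                   censoring_fraction=0.3, seed=seed)
    cohort, truth = simulate_cohort(spec)
    muts = pd.DataFrame({m: [r.features[m] for r in cohort]
                         for m in spec.mutation_names})
    return cohort, muts


class TestGroupCox:
    def test_null_group_ci_covers_one(self):
        covered = 0
        reps = 20
        for rep in range(reps):
            cohort, muts = _mutation_cohort(seed=300 + rep, protective=0.0)
            ind = pd.DataFrame({
                "null": binarize_group(["m5", "m6"], muts)})  # not in hazard
            table = validate_groups_cox(ind, cohort.times, cohort.events)
            row = table.loc["null"]
            covered += row["ci_lower"] <= 1.0 <= row["ci_upper"]
        assert covered >= 0.9 * reps

    def test_planted_protective_group_recovered(self):
        hrs = []
        for rep in range(10):
            cohort, muts = _mutation_cohort(seed=400 + rep, n=500)
            ind = pd.DataFrame({
                "planted": binarize_group(["m1", "m2"], muts)})
            table = validate_groups_cox(ind, cohort.times, cohort.events)
            hrs.append(float(table.loc["planted", "hazard_ratio"]))
        assert np.mean(hrs) == pytest.approx(np.exp(-0.7), abs=0.15)

    def test_constant_indicator_skipped_with_warning(self):
        cohort, muts = _mutation_cohort(seed=5)
        ind = pd.DataFrame({"flat": np.zeros(len(cohort), dtype=int)})
        with pytest.warns(UserWarning, match="constant"):
            table = validate_groups_cox(ind, cohort.times, cohort.events)
        assert len(table) == 0

    def test_simplified_cox_tracks_planted_signal(self):
        cohort, muts = _mutation_cohort(seed=6, n=500)
        planted = pd.DataFrame({
            "planted": binarize_group(["m1", "m2"], muts)})
        rng = np.random.default_rng(0)
        random_ind = pd.DataFrame({
            "random": binarize_group(["m5", "m6"], muts)})
        splits = make_splits(len(cohort), n_splits=5, seed=1)
        good = simplify_to_cox(planted, cohort.times, cohort.events, splits)
        rand = simplify_to_cox(random_ind, cohort.times, cohort.events, splits)
        assert np.nanmean(good["test_c_index"]) > np.nanmean(
            rand["test_c_index"])
        assert {"low", "high"} >= set(np.concatenate(good["risk_labels"]))

    def test_empty_design_fatal(self):
        with pytest.raises(ValueError):
            simplify_to_cox(pd.DataFrame(), [1.0], [1], [])


class TestPermutationImportance:
    def test_feature_absent_everywhere_has_zero_importance(self, small_fit):
        model, res, _ = small_fit
        net = res.networks[0]
        # score against a cohort restricted to half the features
        df = permutation_importance(net, model.cohort, model.L, n_repeats=3,
                                    rng=np.random.default_rng(0),
                                    features=model.vocab.feature_names)
        assert df.shape[1] == 3

    def test_informative_features_rank_top(self, small_fit):
        """f1/f2 carry the hazard; they should head the importance ranking."""
        model, res, truth = small_fit
        df = permutation_importance(res.networks[0], model.cohort, model.L,
                                    n_repeats=10,
                                    rng=np.random.default_rng(1))
        order = df.mean(axis=1).sort_values(ascending=False)
        assert {"f1", "f2"} <= set(order.index[:3])
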