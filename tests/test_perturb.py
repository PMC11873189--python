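"""In-silico perturbation: grid construction, linear-scorer oracles, the
Diff interaction score and variant/invariant population splits."""

from __future__ import annotations

import numpy as np
import pytest

from survformer import Cohort, PatientRecord, Vocabulary
from survformer.perturb import (compare_populations, diff_score,
                                interaction_significance, percentile_grid,
                                perturb_pair, perturb_single,
                                split_variant_invariant)


class LinearScorer:
    """Stand-in network whose score is a fixed linear function of the
    feature values: beta = sum(weight_f * value_f). Lets perturbation
    arithmetic be checked exactly."""

    def __init__(self, weights: dict[str, float], feature_names=None):
        self.weights = weights
        names = feature_names or sorted(weights)
        self.vocab = Vocabulary(list(names))

        class _Cfg:
            max_len = 1 + len(names)
        self.config = _Cfg()

    def survival_scores(self, batch):
        from survformer.autodiff import Tensor
        out = np.zeros(len(batch))
        for b in range(len(batch)):
            for j in np.flatnonzero(~batch.pad_mask[b]):
                tok = batch.token_ids[b, j]
                if tok >= Vocabulary.N_RESERVED:
                    name = self.vocab.name_of(tok)
                    out[b] += self.weights.get(name, 0.0) * batch.values[b, j]
        return Tensor(out), None


def _toy_cohort(values_f, values_g=None):
    records = []
    for i, v in enumerate(values_f):
        feats = {"f": float(v)}
        if values_g is not None:
            feats["g"] = float(values_g[i])
        records.append(PatientRecord(f"P{i}", feats, float(i + 1), 1))
    return Cohort(records)


class TestPercentileGrid:
    def test_decile_midpoints(self):
        vals = np.arange(1.0, 101.0)
        grid = percentile_grid(vals, 10)
        assert len(grid) == 10
        assert grid[0] == pytest.approx(np.percentile(vals, 5))
        assert grid[-1] == pytest.approx(np.percentile(vals, 95))

    def test_few_distinct_values_fall_back_to_uniques(self):
        grid = percentile_grid(np.array([1.0, 1.0, 2.0, 3.0]), 10)
        assert grid.tolist() == [1.0, 2.0, 3.0]


class TestPerturbSingle:
    def test_linear_scorer_delta_is_grid_range(self):
        net = LinearScorer({"f": 1.0})
        cohort = _toy_cohort(np.linspace(-3, 3, 30))
        grid = perturb_single(net, cohort, "f", L=net.config.max_len)
        expected = grid.grid.max() - grid.grid.min()
        assert np.allclose(grid.delta_beta, expected, atol=1e-12)

    def test_insensitive_model_has_zero_delta(self):
        net = LinearScorer({"f": 0.0, "g": 2.0}, feature_names=["f", "g"])
        cohort = _toy_cohort(np.arange(10.0), np.arange(10.0))
        grid = perturb_single(net, cohort, "f", L=net.config.max_len)
        assert np.allclose(grid.delta_beta, 0.0)

    def test_perturbing_to_observed_value_reproduces_baseline(self):
        net = LinearScorer({"f": 1.5})
        cohort = _toy_cohort([2.0])
        grid = perturb_single(net, cohort, "f", L=net.config.max_len,
                              train_cohort=_toy_cohort([2.0, 2.0, 2.0]))
        # grid collapses to the single observed value 2.0
        assert np.allclose(grid.scores, grid.baseline[:, None])

    def test_grid_order_invariance_of_delta(self):
        net = LinearScorer({"f": -0.7})
        cohort = _toy_cohort(np.arange(20.0))
        g1 = perturb_single(net, cohort, "f", L=net.config.max_len)
        assert np.allclose(g1.delta_beta,
                           np.abs(-0.7) * (g1.grid.max() - g1.grid.min()))

    def test_unknown_feature_fatal(self):
        net = LinearScorer({"f": 1.0})
        with pytest.raises(ValueError, match="unknown"):
            perturb_single(net, _toy_cohort([1.0]), "zz", L=net.config.max_len)


class TestPerturbPair:
    def test_seeded_determinism(self):
        net = LinearScorer({"f": 1.0, "g": -1.0}, feature_names=["f", "g"])
        cohort = _toy_cohort(np.arange(12.0), np.arange(12.0)[::-1])
        a = perturb_pair(net, cohort, ("f", "g"), net.config.max_len, cohort,
                         n_repeats=7, rng=np.random.default_rng(3))
        b = perturb_pair(net, cohort, ("f", "g"), net.config.max_len, cohort,
                         n_repeats=7, rng=np.random.default_rng(3))
        assert np.array_equal(a.scores, b.scores)

    def test_self_pair_matches_single_within_mc_error(self):
        net = LinearScorer({"f": 1.0})
        train = _toy_cohort(np.linspace(0, 10, 200))
        cohort = _toy_cohort(np.linspace(0, 10, 40))
        single = perturb_single(net, cohort, "f", net.config.max_len,
                                train_cohort=train)
        paired = perturb_pair(net, cohort, ("f", "f"), net.config.max_len,
                              train, n_repeats=200,
                              rng=np.random.default_rng(0))
        # same scorer, same value source: Delta-beta distributions agree
        assert (np.median(paired.delta_beta)
                == pytest.approx(np.median(single.delta_beta), rel=0.15))

    def test_other_features_held_fixed(self):
        net = LinearScorer({"f": 1.0, "g": 1.0, "h": 10.0},
                           feature_names=["f", "g", "h"])
        records = [PatientRecord(f"P{i}", {"f": 1.0, "g": 1.0, "h": float(i)},
                                 i + 1.0, 1) for i in range(6)]
        cohort = Cohort(records)
        grid = perturb_pair(net, cohort, ("f", "g"), net.config.max_len,
                            cohort, n_repeats=10,
                            rng=np.random.default_rng(1))
        # every donor carries f=g=1, so the perturbed (f, g) part is always
        # 2.0 while the untouched h contributes 10*i per patient
        base_h = 10.0 * np.arange(6)
        assert np.allclose(grid.scores, 2.0 + base_h[:, None], atol=1e-12)


class TestDiff:
    def test_arithmetic_oracle(self):
        assert diff_score(0.1, 0.5, 0.01) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_when_joint_equals_min_marginal(self):
        assert diff_score(0.03, 0.2, 0.03) == pytest.approx(0.0, abs=1e-12)

    def test_sign_logic_base_invariant(self):
        for base in (2.0, np.e, 10.0):
            assert diff_score(0.1, 0.5, 0.01, log_base=base) < 0
            assert diff_score(0.01, 0.5, 0.1, log_base=base) > 0

    def test_null_perturbation_gives_p_near_one(self, rng):
        from survformer.perturb import PerturbationGrid
        base = rng.normal(size=60)
        grid = PerturbationGrid(("f",), np.zeros(1), [f"P{i}" for i in range(60)],
                                base[:, None].copy(), base.copy())
        table = interaction_significance(
            {"f": grid, "g": grid}, {("f", "g"): grid}, base)
        row = table.iloc[0]
        assert row["p_fg"] > 0.8 and abs(row["neglog_p_fg"]) < 0.1


class TestPopulationSplit:
    def _grid(self, deltas, ids=None):
        from survformer.perturb import PerturbationGrid
        n = len(deltas)
        ids = ids or [f"P{i}" for i in range(n)]
        scores = np.zeros((n, 2))
        scores[:, 1] = deltas
        return PerturbationGrid(("f",), np.zeros(2), ids, scores, np.zeros(n))

    def test_even_split_sizes(self, rng):
        grid = self._grid(rng.normal(size=42))
        split = split_variant_invariant(grid)
        assert len(split.variant_ids) == 21 and len(split.invariant_ids) == 21
        assert not set(split.variant_ids) & set(split.invariant_ids)

    def test_variant_has_larger_delta(self, rng):
        deltas = rng.uniform(0, 5, size=30)
        grid = self._grid(deltas)
        split = split_variant_invariant(grid)
        dv = [deltas[int(p[1:])] for p in split.variant_ids]
        di = [deltas[int(p[1:])] for p in split.invariant_ids]
        assert min(dv) >= max(di)

    def test_all_equal_warns_and_balances(self):
        grid = self._grid(np.ones(7))
        with pytest.warns(UserWarning, match="stable"):
            split = split_variant_invariant(grid)
        assert abs(len(split.variant_ids) - len(split.invariant_ids)) <= 1

    def test_restriction_filter(self, rng):
        grid = self._grid(rng.normal(size=20))
        keep = [f"P{i}" for i in range(8)]
        split = split_variant_invariant(grid, restrict_ids=keep)
        assert set(split.patient_ids) == set(keep)
        assert len(split.variant_ids) == 4

    def test_improved_ids_cross_cutoff(self):
        deltas = np.array([0.1, 0.2, 5.0, 6.0])
        grid = self._grid(deltas)
        split = split_variant_invariant(grid, q1_cutoff=1.0)
        assert set(split.improved_ids) == {"P2", "P3"}


class TestCrossBlockInteractions:
    """When the hazard's only interaction couples the two feature blocks
    (log-hazard ~ product of block sums plus main effects), the pairs
    with the most negative Diff should be predominantly cross-block."""

    @staticmethod
    def _product_cohort(seed, n=300, c_int=0.4, c_main=0.25):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 6))
        A = X[:, :3].sum(axis=1)
        B = X[:, 3:].sum(axis=1)
        eta = c_int * A * B / np.sqrt(3) + c_main * (A - B)
        u = rng.uniform(size=n)
        T = -np.log(u) / (np.log(2) / 12 * np.exp(eta))
        C = rng.exponential(T.mean() * 2.2, n)
        recs = [PatientRecord(f"P{i:04d}",
                              {f"f{j + 1}": float(X[i, j]) for j in range(6)},
                              float(min(T[i], C[i])), int(T[i] <= C[i]))
                for i in range(n)]
        return Cohort(recs)

    def test_top_diff_pairs_enriched_for_cross_block(self):
        import itertools

        from scipy import stats as sstats

        from survformer import ModelConfig, TrainPlan, TransformerSurvival

        feats = [f"f{i}" for i in range(1, 7)]

        def is_cross(f, g):
            return (f in feats[:3]) != (g in feats[:3])

        tot_cross = tot_top = 0
        for seed in (60, 61, 62, 63, 64):
            cohort = self._product_cohort(seed)
            model = TransformerSurvival(
                cohort, config=ModelConfig(d_k=32, n_layers=2, n_heads=4),
                plan=TrainPlan(strategy="gradual", pretrain_iters=1000,
                               n_splits=1, finetune_epochs=60, batch_size=64,
                               eval_every=60))
            res = model.fit(seed=0)
            train = cohort[list(res.splits[0][0])]
            net = res.networks[0]
            singles = {f: perturb_single(net, cohort, f, model.L,
                                         train_cohort=train) for f in feats}
            rng = np.random.default_rng(1)
            pairs = {p: perturb_pair(net, cohort, p, model.L, train,
                                     n_repeats=30, rng=rng)
                     for p in itertools.combinations(feats, 2)}
            table = interaction_significance(singles, pairs,
                                             singles["f1"].baseline)
            table["cross"] = [is_cross(r.f, r.g) for r in table.itertuples()]
            top = table.sort_values("diff").head(6)
            tot_cross += int(top["cross"].sum())
            tot_top += len(top)
        # 9 of the 15 pairs are cross-block, so 0.6 is the chance rate
        p = sstats.binomtest(tot_cross, tot_top, 9 / 15,
                             alternative="greater").pvalue
        assert p < 0.05


class TestComparePopulations:
    def _cohort(self, va, vb, feature="x"):
        records = []
        for i, v in enumerate(list(va) + list(vb)):
            records.append(PatientRecord(f"P{i}", {feature: float(v),
                                                   "const": 1.0},
                                         i + 1.0, 1))
        return Cohort(records), \
            [f"P{i}" for i in range(len(va))], \
            [f"P{i}" for i in range(len(va), len(va) + len(vb))]

    def test_identical_groups_not_significant(self, rng):
        from survformer.perturb import PopulationSplit
        vals = rng.normal(size=20)
        cohort, var_ids, inv_ids = self._cohort(vals, vals)
        split = PopulationSplit(var_ids + inv_ids, np.zeros(40), var_ids,
                                inv_ids, [])
        table = compare_populations(split, cohort)
        assert (table["p_bonferroni"] > 0.9).all()
        assert "const" not in set(table["feature"])  # constants skipped

    def test_planted_two_sd_shift_detected(self, rng):
        detected = 0
        reps = 10
        for rep in range(reps):
            r = np.random.default_rng(rep)
            a = r.normal(2.0, 1.0, 21)
            b = r.normal(0.0, 1.0, 21)
            cohort, var_ids, inv_ids = self._cohort(a, b)
            from survformer.perturb import PopulationSplit
            split = PopulationSplit(var_ids + inv_ids, np.zeros(42), var_ids,
                                    inv_ids, [])
            table = compare_populations(split, cohort)
            row = table[table["feature"] == "x"].iloc[0]
            # Bonferroni over a 30-feature panel is the stricter real setting
            detected += row["p_raw"] * 30 < 0.05
        assert detected >= 0.9 * reps

    def test_binary_features_reported_as_proportions(self):
        from survformer.perturb import PopulationSplit
        a = [1, 1, 1, 0, 1, 1]
        b = [0, 0, 1, 0, 0, 0]
        cohort, var_ids, inv_ids = self._cohort(a, b, feature="mut")
        split = PopulationSplit(var_ids + inv_ids, np.zeros(12), var_ids,
                                inv_ids, [])
        table = compare_populations(split, cohort)
        row = table[table["feature"] == "mut"].iloc[0]
        assert row["kind"] == "binary"
        assert row["mean_variant"] == pytest.approx(5 / 6)
        assert row["mean_invariant"] == pytest.approx(1 / 6)
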