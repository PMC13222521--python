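"""CV plans, metrics, paired testing, FDR, ranking and the column shuffle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clcnet.evaluation import (
    bh_adjust,
    compare_models,
    make_cv_plan,
    metric_mse,
    metric_pcc,
    metric_spearman,
    paired_compare,
    rank_models,
    run_cv,
    shuffle_snp_columns,
    significance_stars,
)
from clcnet.select import DESK_GBDT_PARAMS
from clcnet.training import TrainConfig


class TestCvPlan:
    def test_thirty_cells_and_partition_per_repeat(self):
        plan = make_cv_plan(100, seeds=(42, 84, 162), n_folds=10)
        assert len(plan) == 30
        for seed in (42, 84, 162):
            cells = [c for c in plan if c.repeat_seed == seed]
            all_test = np.concatenate([c.test_idx for c in cells])
            assert sorted(all_test.tolist()) == list(range(100))

    def test_inner_split_partitions_outer_train(self):
        plan = make_cv_plan(100, seeds=(42,), n_folds=10)
        for c in plan:
            outer = np.union1d(c.inner_train_idx, c.inner_valid_idx)
            assert len(np.intersect1d(c.inner_train_idx, c.inner_valid_idx)) == 0
            assert len(np.intersect1d(outer, c.test_idx)) == 0
            assert len(outer) + len(c.test_idx) == 100
            frac = len(c.inner_valid_idx) / len(outer)
            assert 0.15 <= frac <= 0.25

    def test_same_seeds_reproduce_plan(self):
        p1 = make_cv_plan(57, seeds=(7, 8), n_folds=5)
        p2 = make_cv_plan(57, seeds=(7, 8), n_folds=5)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.test_idx, b.test_idx)
            assert np.array_equal(a.inner_train_idx, b.inner_train_idx)

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = make_cv_plan(101, seeds=(1,), n_folds=10)
        sizes = [len(c.test_idx) for c in plan]
        assert max(sizes) - min(sizes) <= 1

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(15, seeds=(1,), n_folds=10)


class TestMetrics:
    def test_monotone_affine_gives_perfect_correlations(self, rng):
        y = rng.standard_normal(20)
        assert metric_pcc(y, 2 * y + 1) == pytest.approx(1.0)
        assert metric_spearman(y, 2 * y + 1) == pytest.approx(1.0)
        assert metric_pcc(y, -y) == pytest.approx(-1.0)

    def test_hand_vectors_match_independent_oracles(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        yh = np.array([2.0, 2.0, 3.0, 0.0, 6.0])
        # brute-force sums
        pcc = (np.sum((y - y.mean()) * (yh - yh.mean()))
               / np.sqrt(np.sum((y - y.mean()) ** 2) * np.sum((yh - yh.mean()) ** 2)))
        assert metric_pcc(y, yh) == pytest.approx(pcc, abs=1e-12)
        assert metric_mse(y, yh) == pytest.approx(np.mean((y - yh) ** 2), abs=1e-12)
        # rank oracle with average ties
        ry = pd.Series(y).rank().to_numpy()
        ryh = pd.Series(yh).rank().to_numpy()
        rho = (np.sum((ry - ry.mean()) * (ryh - ryh.mean()))
               / np.sqrt(np.sum((ry - ry.mean()) ** 2) * np.sum((ryh - ryh.mean()) ** 2)))
        assert metric_spearman(y, yh) == pytest.approx(rho, abs=1e-12)

    def test_constant_inputs_flagged_missing(self):
        assert np.isnan(metric_pcc(np.ones(5), np.arange(5.0)))
        assert np.isnan(metric_spearman(np.arange(5.0), np.ones(5)))


def _records(tag, values, seeds=(1, 2), folds=3):
    rows = []
    k = 0
    for s in seeds:
        for f in range(folds):
            rows.append({"model": tag, "repeat_seed": s, "fold": f,
                         "pcc": values[k], "mse": 1.0, "spearman": 0.0,
                         "n_test": 10})
            k += 1
    return pd.DataFrame(rows)


class TestPairedCompare:
    def test_identical_records_give_t_zero_p_one(self):
        a = _records("A", [0.5, 0.6, 0.4, 0.5, 0.7, 0.6])
        r = paired_compare(a, a.assign(model="B"))
        assert r["t"] == 0.0 or np.isnan(r["t"])
        assert r["p"] == 1.0

    def test_constant_positive_difference_degenerate_p(self):
        a = _records("A", [0.5, 0.6, 0.4, 0.5, 0.7, 0.6])
        b = a.assign(model="B", pcc=a["pcc"] - 0.02)
        with pytest.warns(UserWarning, match="zero-variance"):
            r = paired_compare(a, b)
        assert r["p"] == np.finfo(float).tiny and r["mean_diff"] > 0

    def test_matches_closed_form_t_distribution_computation(self, rng):
        for _ in range(50):
            d = rng.normal(0.02, 0.01, 30)
            a = _records("A", np.linspace(0.3, 0.7, 30), seeds=(1, 2, 3), folds=10)
            b = a.assign(model="B", pcc=a["pcc"] - d)
            r = paired_compare(a, b)
            t = d.mean() / (d.std(ddof=1) / np.sqrt(30))
            p = 2 * stats.t.sf(abs(t), 29)
            assert r["p"] == pytest.approx(p, abs=1e-10)

    def test_mismatched_cells_rejected(self):
        a = _records("A", [0.1] * 6)
        b = _records("B", [0.1] * 6, seeds=(1, 3))
        with pytest.raises(ValueError, match="identical"):
            paired_compare(a, b)


class TestBhAdjust:
    def test_hand_worked_example(self):
        adj = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged_and_all_equal_stay_equal(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_brute_force_step_up_oracle(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            out = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(prev, p[i] * m / rank, 1.0)
                out[i] = val
                prev = val
            return out

        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), oracle(p), atol=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(1e-6, 1, 25)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_adjusted_at_least_raw_and_stars(self, rng):
        p = rng.uniform(0, 1, 15)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == "ns"


class TestRankModels:
    def test_rank_by_mean_and_tie_sharing(self):
        recs = pd.concat([
            _records("A", [0.5] * 6), _records("B", [0.4] * 6),
            _records("C", [0.5] * 6)])
        table = rank_models(recs)
        ranks = dict(zip(table["model"], table["rank"]))
        assert ranks["B"] == 3.0
        assert ranks["A"] == ranks["C"] == 1.5

    def test_order_invariance(self):
        recs = pd.concat([_records("A", [0.6] * 6), _records("B", [0.2] * 6)])
        r1 = rank_models(recs)
        r2 = rank_models(recs.iloc[::-1])
        assert dict(zip(r1["model"], r1["rank"])) == dict(zip(r2["model"], r2["rank"]))


class TestShuffleColumns:
    def test_row_multisets_preserved(self, small_fixture):
        G, _, _ = small_fixture
        Gs = shuffle_snp_columns(G, seed=3)
        assert Gs.values.shape == G.values.shape
        for i in range(0, G.n_samples, 25):
            assert sorted(G.values[i].tolist()) == sorted(Gs.values[i].tolist())

    def test_map_slots_stay_and_ids_move(self, small_fixture):
        G, _, _ = small_fixture
        Gs = shuffle_snp_columns(G, seed=3)
        assert np.array_equal(Gs.chrom, G.chrom)
        assert np.array_equal(Gs.pos, G.pos)
        assert not np.array_equal(Gs.snp_ids, G.snp_ids)

    def test_same_seed_same_permutation(self, small_fixture):
        G, _, _ = small_fixture
        a, b = shuffle_snp_columns(G, 9), shuffle_snp_columns(G, 9)
        assert np.array_equal(a.values, b.values)

    def test_single_snp_identity(self):
        from clcnet.geno import GenotypeMatrix

        G = GenotypeMatrix(np.array([[1], [0]]), ["a", "b"], ["s"], ["1"], [5])
        assert np.array_equal(shuffle_snp_columns(G, 0).values, G.values)


class TestRunCv:
    def test_record_count_and_ridge_signal_floor(self, small_fixture):
        G, y, _ = small_fixture
        plan = make_cv_plan(G.n_samples, seeds=(42, 84), n_folds=5)
        df = run_cv(G, y, plan, model="ridge", selection="none")
        assert len(df) == 10
        assert (df["error"] == "").all()
        assert df["pcc"].mean() > 0    # heritable trait: signal exists

    def test_null_trait_pcc_within_null_band(self, small_fixture):
        G, _, _ = small_fixture
        y = np.random.default_rng(12).standard_normal(G.n_samples)
        plan = make_cv_plan(G.n_samples, seeds=(42, 84), n_folds=5)
        df = run_cv(G, y, plan, model="ridge", selection="none")
        n_test = df["n_test"].mean()
        assert abs(df["pcc"].mean()) < 2 / np.sqrt(n_test)

    def test_gbdt_baseline_and_compare_models_table(self, small_fixture):
        G, y, _ = small_fixture
        plan = make_cv_plan(G.n_samples, seeds=(42,), n_folds=5)
        a = run_cv(G, y, plan, model="ridge", selection="none", model_tag="ridge")
        b = run_cv(G, y, plan, model="gbdt", selection="none",
                   gbdt_params=DESK_GBDT_PARAMS, model_tag="gbdt")
        table = compare_models(pd.concat([a, b]), reference="ridge")
        assert set(table.columns) >= {"model", "mean_diff", "p", "p_adj", "stars"}
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
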