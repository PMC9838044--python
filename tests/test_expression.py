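"""Expression calls, breadth histograms, background contrast, trends, clustering."""

import numpy as np
import pandas as pd
import pytest

from hdzip import expression, simulate, validation
from hdzip.expression import (
    Design,
    ExpressionMatrix,
    age_trend_genes,
    breadth_distribution,
    call_expressed,
    cluster_samples,
    compare_with_random_background,
    core_gene_set,
    percent_at_least,
)


def _df(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestCallExpressed:
    def test_strict_threshold_boundary(self):
        df = _df([[0.0, 0.5, 1.0]])
        assert call_expressed(df).to_numpy().tolist() == [[False, True, True]]
        assert call_expressed(df, 1.0).to_numpy().tolist() == [[False, False, False]]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        df = _df(rng.exponential(1.0, (30, 6)))
        k_lo = call_expressed(df, 0.0).sum(axis=1)
        k_hi = call_expressed(df, 1.0).sum(axis=1)
        assert (k_hi <= k_lo).all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_expressed(_df([[1.0]]), -1.0)


class TestBreadth:
    def test_bins_match_direct_enumeration(self):
        rng = np.random.default_rng(1)
        b = pd.DataFrame(rng.random((20, 6)) < 0.5)
        dist = breadth_distribution(b)
        direct = np.bincount(b.to_numpy().sum(axis=1), minlength=7)
        assert dist["count"].to_numpy().tolist() == direct.tolist()
        assert dist["count"].sum() == 20

    def test_published_percentages(self):
        # 95 of 117 genes expressed in >=1 sample; 34 of 117 in all samples
        b = pd.DataFrame(
            [[True] * 4] * 34 + [[True, False, False, False]] * 61
            + [[False] * 4] * 22
        )
        assert round(percent_at_least(b, 1), 1) == 81.2
        dist = breadth_distribution(b)
        assert round(float(dist.loc[4, "percent"]), 1) == 29.1

    def test_gene_in_all_samples_lands_in_top_bin(self):
        b = pd.DataFrame([[True, True, True, True]])
        assert breadth_distribution(b)["count"][4] == 1


class TestBackgroundComparison:
    def test_extreme_separation(self):
        genes = [f"t{i}" for i in range(10)] + [f"p{i}" for i in range(40)]
        vals = np.zeros((50, 4))
        vals[:10] = 1.0  # target fully expressed, pool silent
        res = compare_with_random_background(genes[:10], genes[10:],
                                             _df(vals, genes), seed=0)
        assert res.target_at_least_one == 10
        assert res.random_at_least_one.max() == 0
        assert res.p_value < 1e-6 and res.significant

    def test_direction_of_planted_contrast(self):
        m, truth = simulate.gen_expression(
            n_family=117, n_pool=1000, design=Design.AGES4,
            breadth_spec=simulate.DEFAULT_AGES4_BREADTH,
            pool_expressed_fraction=0.4, seed=2,
        )
        res = compare_with_random_background(
            truth["family_ids"], truth["pool_ids"], m, seed=3,
        )
        assert res.target_at_least_one == 95
        assert res.target_at_least_one > res.random_at_least_one.mean()
        assert res.significant

    def test_pool_too_small(self):
        df = _df(np.ones((5, 4)))
        with pytest.raises(ValueError, match="pool smaller"):
            compare_with_random_background(df.index[:4], df.index[3:], df)

    def test_n_boot_recorded(self):
        df = _df(np.random.default_rng(4).random((30, 4)))
        res = compare_with_random_background(df.index[:5], df.index[5:], df,
                                             n_boot=20, seed=5)
        assert res.n_boot == 20 and len(res.random_at_least_one) == 20


class TestCoreGeneSet:
    def test_planted_ubiquitous_genes(self):
        m_a, truth = simulate.gen_expression(
            60, 0, Design.AGES4, breadth_spec={0: 20, 2: 21, 4: 19}, seed=6)
        m_t, _ = simulate.gen_expression(
            60, 0, Design.TISSUES14, breadth_spec={0: 20, 7: 21, 14: 19}, seed=7)
        core = core_gene_set({
            "ages4": call_expressed(m_a), "tissues14": call_expressed(m_t),
        })
        planted_a = {g for g, k in truth["breadth_class"].items() if k == 4}
        assert len(core) == 19
        assert core <= planted_a

    def test_core_subset_of_each_design(self):
        rng = np.random.default_rng(8)
        b1 = _df(rng.exponential(1, (30, 4)) * (rng.random((30, 4)) < 0.8))
        b2 = _df(rng.exponential(1, (30, 14)) * (rng.random((30, 14)) < 0.8))
        core = core_gene_set({"a": call_expressed(b1), "b": call_expressed(b2)})
        for df in (b1, b2):
            allset = set(df.index[call_expressed(df).all(axis=1)])
            assert core <= allset

    def test_mismatched_universe_errors(self):
        b1 = call_expressed(_df(np.ones((3, 4))))
        b2 = call_expressed(_df(np.ones((4, 4))))
        with pytest.raises(ValueError, match="universe"):
            core_gene_set({"a": b1, "b": b2})


class TestAgeTrends:
    def test_doubling_profile(self):
        trends = age_trend_genes(_df([[1, 2, 4, 8]], genes=["up"]))
        assert len(trends) == 1
        t = trends[0]
        assert (t.gene_id, t.direction, t.fold_span) == ("up", "increasing", 8.0)

    def test_constant_and_nonmonotone_excluded(self):
        trends = age_trend_genes(_df([[2, 2, 2, 2], [1, 3, 2, 4]]))
        assert trends == []

    def test_matches_direct_rule_on_noisy_fixture(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.5, 4.0, (50, 4))
        df = _df(vals)
        got = {(t.gene_id, t.direction) for t in age_trend_genes(df, min_fold=2.0)}
        want = set()
        for g, row in zip(df.index, vals):
            d = np.diff(row)
            if (d > 0).all() and row.max() / row.min() >= 2.0:
                want.add((g, "increasing"))
            if (d < 0).all() and row.max() / row.min() >= 2.0:
                want.add((g, "decreasing"))
        assert got == want


class TestClusterSamples:
    def test_two_perfect_blocks(self):
        base = np.arange(1, 11, dtype=float)
        cols = [base, base * 2, -base, -base * 3]  # rho +1 within, -1 across
        df = _df(np.exp(np.column_stack(cols)) , genes=[f"g{i}" for i in range(10)],
                 samples=list("abcd"))
        labels = cluster_samples(df, k_groups=2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_identical_samples_deterministic(self):
        df = _df(np.tile(np.arange(5.0), (4, 1)).T, samples=list("abcd"))
        l1 = cluster_samples(df, k_groups=2)
        l2 = cluster_samples(df, k_groups=2)
        assert (l1 == l2).all()
        assert set(l1) <= {1, 2}

    def test_constant_column_warns(self):
        vals = np.random.default_rng(3).random((8, 4))
        vals[:, 3] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            labels = cluster_samples(_df(vals), k_groups=2)
        assert len(labels) == 4

    def test_planted_split_recovery(self):
        assert validation.sample_clustering_recovery(n_runs=50, seed=0) >= 0.90
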