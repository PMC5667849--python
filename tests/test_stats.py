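import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from genevista import (
    ExpressionProfileModel,
    ExpressionStatsResults,
    bh_qvalues,
    build_stats_table,
)
from genevista.model import FLAG_DEGENERATE, FLAG_INSUFFICIENT, FLAG_OK
from tests.conftest import dataset_from_frames, simulated_fit


def tiny_dataset(rows, groups=("A", "B"), reps=3):
    """Build a dataset from {gene: flat replicate list} dicts."""
    headers = [f"{g}{r + 1}" for g in groups for r in range(reps)]
    lines = ["gene," + ",".join(headers)]
    for gene, vals in rows.items():
        lines.append(gene + "," + ",".join(str(v) for v in vals))
    return dataset_from_frames(
        pd.read_csv(io.StringIO("\n".join(lines) + "\n"), index_col=0))


class TestGroupSummary:
    def test_demo_hand_arithmetic(self, demo_stats):
        # A1BG STOMACH (262, 236, 284) and A2M SALIVARY_GLAND replicates
        assert demo_stats.group_means.at["A1BG", "STOMACH"] == pytest.approx(
            260.667, abs=1e-3)
        assert demo_stats.group_sems.at["A1BG", "STOMACH"] == pytest.approx(
            13.87, abs=0.005)
        assert demo_stats.group_means.at["A2M", "SALIVARY_GLAND"] == (
            pytest.approx(155164.33, abs=0.01))
        assert demo_stats.group_sems.at["A1BG", "SALIVARY_GLAND"] == (
            pytest.approx(140.0504 / np.sqrt(3), abs=1e-3))

    def test_constant_replicates_have_zero_sem(self):
        stats = ExpressionProfileModel(
            tiny_dataset({"g1": [5, 5, 5, 1, 2, 3]})).fit()
        assert stats.group_sems.at["g1", "A"] == 0.0

    @given(a=st.floats(0, 1e4), d=st.floats(0.01, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_sem_closed_form_arithmetic_progression(self, a, d):
        # replicates (a, a+d, a+2d) have sd d, hence SEM d/sqrt(3)
        stats = ExpressionProfileModel(
            tiny_dataset({"g1": [a, a + d, a + 2 * d, 0, 0, 1]})).fit()
        assert stats.group_sems.at["g1", "A"] == pytest.approx(
            d / np.sqrt(3), rel=1e-9)

    def test_missing_replicate_reduces_n_and_flags(self):
        ds = dataset_from_frames(pd.DataFrame(
            {"A1": [1.0], "A2": [2.0], "A3": [np.nan], "B1": [4.0],
             "B2": [5.0]}, index=pd.Index(["g1"], name="gene")))
        stats = ExpressionProfileModel(ds).fit()
        assert stats.group_ns.at["g1", "A"] == 2
        ds2 = dataset_from_frames(pd.DataFrame(
            {"A1": [1.0], "A2": [np.nan], "A3": [np.nan], "B1": [4.0],
             "B2": [5.0]}, index=pd.Index(["g1"], name="gene")))
        stats2 = ExpressionProfileModel(ds2).fit()
        assert stats2.anova.at["g1", "flag"] == FLAG_INSUFFICIENT
        assert np.isnan(stats2.anova.at["g1", "p"])


class TestAnova:
    def test_f_equals_pooled_t_squared_two_groups(self):
        rng = np.random.default_rng(3)
        rows = {f"g{i}": rng.gamma(2, 50, size=6).round(3) for i in range(20)}
        stats = ExpressionProfileModel(tiny_dataset(rows)).fit()
        ds = tiny_dataset(rows)
        for gene in stats.genes:
            a = ds.expr.data.loc[gene, "A"].to_numpy(float)
            b = ds.expr.data.loc[gene, "B"].to_numpy(float)
            t, p = sps.ttest_ind(a, b, equal_var=True)
            F = stats.anova.at[gene, "F"]
            np.testing.assert_allclose(F, t ** 2, rtol=1e-11)
            np.testing.assert_allclose(stats.anova.at[gene, "p"], p,
                                       rtol=1e-11)

    def test_matches_scipy_f_oneway_three_groups(self):
        rng = np.random.default_rng(4)
        rows = {f"g{i}": rng.gamma(2, 50, size=9).round(3) for i in range(15)}
        ds = tiny_dataset(rows, groups=("A", "B", "C"))
        stats = ExpressionProfileModel(ds).fit()
        for gene in stats.genes:
            sample = [ds.expr.data.loc[gene, g].to_numpy(float)
                      for g in ("A", "B", "C")]
            F, p = sps.f_oneway(*sample)
            np.testing.assert_allclose(stats.anova.at[gene, "F"], F,
                                       rtol=1e-10)
            np.testing.assert_allclose(stats.anova.at[gene, "p"], p,
                                       rtol=1e-10)

    def test_identical_groups_give_f_zero_p_one(self):
        stats = ExpressionProfileModel(
            tiny_dataset({"g1": [1, 2, 3, 1, 2, 3]})).fit()
        assert stats.anova.at["g1", "F"] == pytest.approx(0.0)
        assert stats.anova.at["g1", "p"] == pytest.approx(1.0)

    def test_zero_variance_degeneracies(self):
        stats = ExpressionProfileModel(tiny_dataset({
            "flat": [5, 5, 5, 5, 5, 5],        # no variance anywhere
            "shift": [5, 5, 5, 9, 9, 9],       # pure between-group shift
        })).fit()
        assert stats.anova.at["flat", "p"] == 1.0
        assert stats.anova.at["flat", "flag"] == FLAG_OK
        assert stats.anova.at["shift", "p"] == 0.0
        assert stats.anova.at["shift", "flag"] == FLAG_DEGENERATE

    def test_agrees_with_exhaustive_permutation_oracle(self):
        # 2 groups x 4 replicates: enumerate all C(8,4)=70 label assignments
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(12):
            vals = np.abs(rng.normal(50, 10, size=8)).round(2)
            stats = ExpressionProfileModel(
                tiny_dataset({"g": vals}, reps=4)).fit()
            p_f = stats.anova.at["g", "p"]

            def f_stat(a, b):
                grand = np.concatenate([a, b]).mean()
                ssb = 4 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
                ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                return (ssb / 1) / (ssw / 6)

            obs = f_stat(vals[:4], vals[4:])
            perm = [f_stat(vals[list(idx)],
                           vals[[i for i in range(8) if i not in idx]])
                    for idx in itertools.combinations(range(8), 4)]
            p_perm = np.mean([f >= obs - 1e-12 for f in perm])
            diffs.append(abs(p_f - p_perm))
        # the exact permutation p has granularity 1/70 and small-sample
        # parametric/exact disagreement; they should track closely on average
        assert np.mean(diffs) < 0.06
        assert max(diffs) < 0.15

    def test_null_simulation_pvalues_uniform(self):
        stats, _ = simulated_fit(n_genes=2000, n_groups=3, n_reps=3,
                                 de_fraction=0.0, seed=5)
        p = stats.anova["p"].to_numpy()
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * se
        assert sps.kstest(p, "uniform").pvalue > 0.01


class TestPairwise:
    def test_demo_log2fc_a2m(self, demo_dataset):
        stats = ExpressionProfileModel(demo_dataset, pseudocount=0.0).fit()
        lfc = stats.log2fc("SALIVARY_GLAND", "STOMACH")
        assert lfc["A2M"] == pytest.approx(np.log2(155164.333 / 113301.0),
                                           abs=1e-4)
        assert lfc["A2M"] == pytest.approx(0.4537, abs=5e-4)

    def test_self_contrast_is_zero(self, demo_stats):
        assert (demo_stats.log2fc("STOMACH", "STOMACH") == 0).all()

    def test_antisymmetry(self, small_sim):
        stats, _ = small_sim
        a, b = stats.groups[0], stats.groups[2]
        pd.testing.assert_series_equal(stats.log2fc(a, b),
                                       -stats.log2fc(b, a))

    def test_number_of_contrasts(self):
        stats, _ = simulated_fit(n_genes=10, n_groups=5, n_reps=2, seed=1)
        assert len(stats.pairwise) == 5 * 4 // 2

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(7)
        rows = {f"g{i}": rng.gamma(2, 50, size=6).round(3) for i in range(20)}
        ds = tiny_dataset(rows)
        stats = ExpressionProfileModel(ds).fit()
        frame = stats.pairwise[("A", "B")]
        for gene in stats.genes:
            a = ds.expr.data.loc[gene, "A"].to_numpy(float)
            b = ds.expr.data.loc[gene, "B"].to_numpy(float)
            t, p = sps.ttest_ind(a, b, equal_var=False)
            np.testing.assert_allclose(frame.at[gene, "t"], t, rtol=1e-10)
            np.testing.assert_allclose(frame.at[gene, "p"], p, rtol=1e-10)

    def test_zero_variance_pairs(self):
        stats = ExpressionProfileModel(tiny_dataset({
            "flat": [5, 5, 5, 5, 5, 5],
            "shift": [5, 5, 5, 9, 9, 9],
        })).fit()
        frame = stats.pairwise[("A", "B")]
        assert frame.at["flat", "p"] == 1.0
        assert frame.at["shift", "p"] == 0.0
        assert frame.at["shift", "flag"] == FLAG_DEGENERATE


class TestBHQvalues:
    def test_hand_evaluated_examples(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_qvalues([0.2]), [0.2])
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0]), [1.0, 1.0])
        # step-up worked by hand: sorted p*(m/rank) then cummin from the top
        # sorted p*(m/rank): .02, .06, .0533, .9; cummin from the top pulls
        # rank 2 down to .0533
        np.testing.assert_allclose(
            bh_qvalues([0.005, 0.04, 0.03, 0.9]),
            [0.02, 0.16 / 3, 0.16 / 3, 0.9], rtol=1e-12)

    def test_nan_propagates(self):
        q = bh_qvalues([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_qvalues([0.01, 0.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels_and_invariants(self, p):
        p = np.array(p)
        q = bh_qvalues(p)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, rtol=1e-10, atol=1e-12)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        # permutation equivariance
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(bh_qvalues(p[perm]), q[perm])


class TestStatsTable:
    def test_demo_dimensions(self, demo_stats):
        assert len(demo_stats.genes) == 23
        assert len(demo_stats.pairwise) == 1
        assert demo_stats.anova["df_between"].iloc[0] == 1
        assert (demo_stats.anova["df_within"] == 4).all()

    def test_persist_reload_identical(self, demo_dataset, tmp_path):
        path = tmp_path / "lookup.csv"
        stats = build_stats_table(demo_dataset, cache_path=path)
        first = path.read_bytes()
        reloaded = build_stats_table(demo_dataset, cache_path=path)
        assert reloaded.input_hash == stats.input_hash
        pd.testing.assert_frame_equal(reloaded.to_frame(), stats.to_frame())
        # rebuilding from scratch is byte-identical
        path2 = tmp_path / "lookup2.csv"
        build_stats_table(demo_dataset, cache_path=path2)
        assert path2.read_bytes() == first

    def test_stale_cache_recomputed(self, demo_dataset, tmp_path):
        path = tmp_path / "lookup.csv"
        build_stats_table(demo_dataset, cache_path=path)
        stats2 = build_stats_table(demo_dataset, epsilon=2.0, cache_path=path)
        assert stats2.epsilon == 2.0

    def test_planted_genes_top_anova_ranks(self):
        stats, truth = simulated_fit(n_genes=300, n_groups=3, n_reps=4,
                                     de_fraction=0.05, effect=2.0,
                                     noise=0.5, seed=21)
        n_de = len(truth.de_genes)
        rank = stats.anova["q"].rank(method="first")
        de_ranks = rank[truth.de_genes]
        # tests run on the raw expression scale, where lognormal noise
        # inflates within-group variance for the shifted group, so the
        # separation is strong but not perfect
        assert (de_ranks <= 3 * n_de).all()   # all inside the top 15%
        assert (de_ranks <= n_de).mean() >= 0.8

    def test_summary_mentions_counts(self, demo_stats):
        text = demo_stats.summary()
        assert "23" in text and "Pairwise contrasts" in text
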