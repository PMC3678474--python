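"""Orchestration: per-category runs, clade restriction, regressions."""

import numpy as np
import pandas as pd
import pytest

from coralpd import (ThreatTable, TreeSample, published_summary, regress,
                     results_frame, run_all, run_category, run_clade)
from coralpd.analysis import derive_rng
from coralpd.synthetic import (CategorySpec, SyntheticSpec, coral_preset,
                               generate_threat_table, generate_tree_sample)


@pytest.fixture(scope="module")
def small_sample():
    """5 independent 100-tip trees over one label set."""
    spec = SyntheticSpec(n_tips=100, root_age=100.0, clade_split=0.5,
                         age_power=1.0, imbalance_bias=1.0, n_trees=5,
                         seed=21)
    return generate_tree_sample(spec)


@pytest.fixture(scope="module")
def small_table(small_sample):
    spec = SyntheticSpec(n_tips=100, root_age=100.0, clade_split=0.5,
                         age_power=1.0, imbalance_bias=1.0, n_trees=5,
                         seed=21,
                         categories=[CategorySpec("clumped", 0.3, 1.0),
                                     CategorySpec("random", 0.3, 0.0)])
    return generate_threat_table(small_sample[0], spec, derive_rng(21, 5))


class TestRunCategory:
    def test_percent_species_bookkeeping(self, small_sample, small_table):
        trait = small_table.trait("clumped")
        res = run_category(small_sample, trait, reps=100, seed=0)
        assert res.percent_species == pytest.approx(30.0)
        assert res.n_trees == 5
        assert len(res.per_tree) == 5

    def test_identical_trees_small_sd(self, small_sample, small_table):
        """On identical trees D varies only by Monte-Carlo noise."""
        same = TreeSample([small_sample[0].copy() for _ in range(5)])
        res = run_category(same, small_table.trait("clumped"), reps=300,
                           seed=1)
        assert res.d_sd < 0.1

    def test_bit_reproducible(self, small_sample, small_table):
        a = run_category(small_sample, small_table.trait("random"),
                         reps=100, seed=7)
        b = run_category(small_sample, small_table.trait("random"),
                         reps=100, seed=7)
        pd.testing.assert_frame_equal(a.per_tree, b.per_tree)

    def test_monomorphic_reported_not_raised(self, small_sample):
        from coralpd import TraitVector
        labs = small_sample.tip_labels
        trait = TraitVector({l: 0 for l in labs}, name="nobody")
        res = run_category(small_sample, trait, reps=50, seed=0)
        assert not res.defined
        assert np.isnan(res.d_mean)

    def test_clustered_category_loses_more_pd(self):
        """Full-stage calibration: a fully clumped trait on coral-like
        trees destroys more PD than random and shows low D."""
        spec = coral_preset(n_tips=200, n_trees=5, seed=3)
        sample = generate_tree_sample(spec)
        table = generate_threat_table(sample[0], spec, derive_rng(3, 5))
        res = run_category(sample, table.trait("cots"), reps=300, seed=3)
        assert res.pdelta_mean > 0
        assert res.d_mean < 0.3


class TestRunAll:
    def test_row_order_and_permutation(self, small_sample, small_table):
        res = run_all(small_sample, small_table, reps=100, seed=2)
        assert [r.category for r in res] == ["clumped", "random"]
        flipped = ThreatTable(small_table.df[["random", "clumped"]])
        res2 = run_all(small_sample, flipped, reps=100, seed=2)
        assert [r.category for r in res2] == ["random", "clumped"]
        # same numbers, rows permuted only
        assert res2[1].d_mean == pytest.approx(res[0].d_mean)
        assert res2[0].pdelta_mean == pytest.approx(res[1].pdelta_mean)

    def test_doubling_reps_stable(self, small_sample, small_table):
        a = run_category(small_sample, small_table.trait("clumped"),
                         reps=200, seed=5)
        b = run_category(small_sample, small_table.trait("clumped"),
                         reps=400, seed=6)
        null_se = (a.per_tree["null_sd"] / a.per_tree["null_mean"]
                   * 100 / np.sqrt(200)).mean()
        assert abs(a.pdelta_mean - b.pdelta_mean) < 3 * null_se

    def test_alignment_fills_and_drops(self, small_sample, small_table):
        df = small_table.df.copy()
        df = df.drop(df.index[:3])                      # unassessed tips
        df.loc["ghost_species"] = [1, 0]                # not in the trees
        table = ThreatTable(df).aligned_to(small_sample.tip_labels)
        assert "ghost_species" not in table.species
        assert len(table.species) == 100
        assert table.df.loc[small_table.df.index[0]].sum() == 0


class TestRunClade:
    def test_clade_sizes(self):
        spec = SyntheticSpec(n_tips=200, root_age=100.0, clade_split=0.55,
                             age_power=1.0, imbalance_bias=1.0, n_trees=2,
                             seed=9,
                             categories=[CategorySpec("x", 0.3, 0.5)])
        sample = generate_tree_sample(spec)
        from coralpd import root_daughter_clades
        a, b = root_daughter_clades(sample[0])
        assert sorted([len(a), len(b)]) == [90, 110]
        table = generate_threat_table(sample[0], spec, derive_rng(9, 2))
        res1 = run_clade(sample, table, "first", reps=50, seed=9)
        res2 = run_clade(sample, table, "second", reps=50, seed=9)
        n1 = res1[0].per_tree  # ran on the pruned clade trees
        assert n1 is not None
        # prevalence is recomputed relative to the clade species count
        k1 = int(table.df["x"].loc[sorted(a)].sum())
        assert res1[0].percent_species == pytest.approx(100 * k1 / len(a))

    def test_trait_confined_to_one_clade(self):
        spec = SyntheticSpec(n_tips=60, root_age=50.0, clade_split=0.5,
                             age_power=1.0, imbalance_bias=1.0, n_trees=2,
                             seed=13,
                             categories=[CategorySpec("x", 0.2, 0.0)])
        sample = generate_tree_sample(spec)
        labs1, labs2 = (sorted(s) for s in
                        __import__("coralpd").root_daughter_clades(
                            sample[0]))
        df = pd.DataFrame({"only1": [1 if l in set(labs1[:6]) else 0
                                     for l in sample.tip_labels]},
                          index=pd.Index(sample.tip_labels, name="species"))
        table = ThreatTable(df)
        res2 = run_clade(sample, table, "second", reps=50, seed=13)
        assert not res2[0].defined


class TestRegress:
    def test_exact_line(self):
        df = pd.DataFrame({
            "d_mean": np.linspace(0, 1, 8),
            "pdelta_mean": 2 - 5 * np.linspace(0, 1, 8),
            "percent_species": np.linspace(10, 80, 8)})
        s = regress(df, predictor="D", mode="on_means")
        assert s.slope == pytest.approx(-5.0)
        assert s.r_squared == pytest.approx(1.0)
        assert s.p_value < 1e-10

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"d_mean": [0.5] * 5,
                           "pdelta_mean": [1, 2, 3, 4, 5],
                           "percent_species": [10] * 5})
        with pytest.raises(ValueError, match="constant"):
            regress(df, predictor="D")

    def test_prevalence_uses_fractions(self):
        rs = np.random.default_rng(0)
        x = rs.uniform(0, 1, 8)
        df = pd.DataFrame({"percent_species": 100 * x,
                           "pdelta_mean": 3 * x + rs.normal(0, 0.01, 8),
                           "d_mean": x})
        s = regress(df, predictor="prevalence")
        assert s.slope == pytest.approx(3.0, abs=0.1)

    def test_per_tree_mode(self, small_sample, small_table):
        spec = coral_preset(n_tips=150, n_trees=4, seed=17)
        sample = generate_tree_sample(spec)
        table = generate_threat_table(sample[0], spec, derive_rng(17, 4))
        res = run_all(sample, table, reps=100, seed=17)
        s = regress(res, predictor="D", mode="per_tree")
        assert s.n_points == 8
        assert s.slope_ci_low is not None
        assert s.slope_ci_low <= s.slope <= s.slope_ci_high

    def test_headline_negative_rank_correlation(self):
        """With clustering weight as the only varied generator knob,
        mean %dE(PD) is negatively rank-correlated with mean D."""
        from scipy.stats import spearmanr
        ws = np.linspace(0, 1, 8)
        spec = SyntheticSpec(
            n_tips=200, root_age=365.0, clade_split=0.55, age_power=2.5,
            imbalance_bias=1.0, n_trees=5, seed=31,
            categories=[CategorySpec(f"w{i}", 0.3, float(w))
                        for i, w in enumerate(ws)])
        sample = generate_tree_sample(spec)
        table = generate_threat_table(sample[0], spec, derive_rng(31, 5))
        res = run_all(sample, table, reps=200, seed=31)
        d = [r.d_mean for r in res]
        p = [r.pdelta_mean for r in res]
        rho = spearmanr(d, p)
        assert rho.statistic < 0
        assert rho.pvalue < 0.05


class TestPublishedTable:
    def test_blocks_shape(self):
        for block in ("scleractinia", "mtdna", "complex", "robust"):
            df = published_summary(block)
            assert len(df) == 8
            assert (df["percent_species"] > 0).all()
            assert (df["percent_species"] < 100).all()

    def test_results_frame_columns_match(self, small_sample, small_table):
        res = run_all(small_sample, small_table, reps=50, seed=0)
        ours = results_frame(res)
        theirs = published_summary()
        for col in ("percent_species", "d_mean", "d_sd", "pdelta_mean",
                    "pdelta_sd"):
            assert col in ours.columns and col in theirs.columns
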