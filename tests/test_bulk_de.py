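from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import relapse_score as rs
from relapse_score.bulk_and_de import _wilcoxon_p
from conftest import make_counts


def enumeration_wilcoxon_p(x, y):
    """Exact two-sided rank-sum p by exhaustive enumeration of all splits."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[:n].sum()
    sums = np.array([ranks[list(c)].sum() for c in combinations(range(len(pooled)), n)])
    cdf = (sums <= obs).mean()
    sf = (sums >= obs).mean()
    return min(1.0, 2 * min(cdf, sf))


def _norm_df(X):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X, index=[f"c{i}" for i in range(X.shape[0])],
        columns=[f"g{j}" for j in range(X.shape[1])],
    )


class TestWilcoxon:
    @pytest.mark.parametrize("n,m", [(3, 3), (4, 6), (5, 5), (8, 7)])
    def test_matches_exhaustive_enumeration(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            assert _wilcoxon_p(x, y) == pytest.approx(enumeration_wilcoxon_p(x, y), abs=1e-12)

    def test_separated_five_vs_five(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([6.0, 7, 8, 9, 10])
        # most extreme split: p = 2 / C(10,5)
        assert _wilcoxon_p(x, y) == pytest.approx(2 / 252)
        assert _wilcoxon_p(x, y) == pytest.approx(enumeration_wilcoxon_p(x, y))

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(123)
        n_genes, n_cells = 200, 100
        X = rng.normal(size=(2 * n_cells, n_genes))
        labels = pd.Series(
            ["sensitive"] * n_cells + ["resistant"] * n_cells,
            index=[f"c{i}" for i in range(2 * n_cells)],
        )
        de = rs.differential_expression(_norm_df(X), labels, min_pct=0.0)
        frac = (de["p"] < 0.05).mean()
        lo, hi = scipy.stats.binom.interval(0.99, n_genes, 0.05)
        assert lo / n_genes <= frac <= hi / n_genes


class TestDifferentialExpression:
    def test_identical_groups_no_signal(self):
        rng = np.random.default_rng(1)
        block = rng.random((12, 15))
        X = np.vstack([block, block])
        labels = pd.Series(["sensitive"] * 12 + ["resistant"] * 12,
                           index=[f"c{i}" for i in range(24)])
        de = rs.differential_expression(_norm_df(X), labels)
        np.testing.assert_allclose(de["lnFC"], 0.0, atol=1e-12)
        assert not de["significant"].any()

    def test_min_pct_prefilter(self):
        X = np.zeros((20, 2))
        X[0, 0] = 1.0  # gene 0 expressed in 1/10 of group A only
        X[:, 1] = np.arange(20.0) + 1
        labels = pd.Series(["sensitive"] * 10 + ["resistant"] * 10,
                           index=[f"c{i}" for i in range(20)])
        de = rs.differential_expression(_norm_df(X), labels, min_pct=0.5)
        assert not de.loc["g0", "tested"]
        assert de.loc["g1", "tested"]
        assert de.attrs["n_tested"] == 1

    def test_empty_group_rejected(self):
        labels = pd.Series(["sensitive"] * 4, index=[f"c{i}" for i in range(4)])
        with pytest.raises(ValueError, match="non-empty"):
            rs.differential_expression(_norm_df(np.random.rand(4, 3)), labels)

    def test_ln_fold_change_definition(self):
        X = np.log1p(np.array([[3.0, 0.0]] * 5 + [[1.0, 0.0]] * 5))
        labels = pd.Series(["sensitive"] * 5 + ["resistant"] * 5,
                           index=[f"c{i}" for i in range(10)])
        de = rs.differential_expression(_norm_df(X), labels, min_pct=0.0)
        assert de.loc["g0", "lnFC"] == pytest.approx(np.log(4) - np.log(2))


class TestGeneScoreCorrelation:
    def _scores(self, sens, res):
        idx = [f"c{i}" for i in range(len(sens))]
        return pd.DataFrame(
            {"sensitivity_score": sens, "resistance_score": res, "pc_score": 0.0},
            index=idx,
        )

    def test_gene_equal_to_score_has_rho_one(self):
        sens = np.array([0.1, 0.9, 0.4, 0.7, 0.2])
        X = np.column_stack([sens, np.random.default_rng(0).random(5)])
        out = rs.correlate_genes_with_scores(_norm_df(X), self._scores(sens, -sens))
        assert out.loc["g0", "rho_sensitivity"] == pytest.approx(1.0)
        assert out.loc["g0", "rho_resistance"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_missing(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        out = rs.correlate_genes_with_scores(
            _norm_df(X), self._scores(np.arange(5.0), np.arange(5.0))
        )
        assert np.isnan(out.loc["g0", "rho_sensitivity"])

    def test_matches_rank_then_pearson_by_hand(self):
        rng = np.random.default_rng(7)
        X = rng.random((5, 3))
        sens = rng.random(5)
        out = rs.correlate_genes_with_scores(_norm_df(X), self._scores(sens, sens))
        for j in range(3):
            expected = scipy.stats.spearmanr(X[:, j], sens)[0]
            assert out.loc[f"g{j}", "rho_sensitivity"] == pytest.approx(expected)


class TestPseudobulk:
    def test_complete_mode_is_addition(self):
        counts = make_counts([[1, 2, 0], [0, 1, 3]])
        pooled = rs.pool_bulk(counts, pd.Series("S1", index=counts.obs_names), mode="complete")
        np.testing.assert_array_equal(pooled.profiles.loc["S1"], [1, 3, 3])

    def test_complete_mode_preserves_mass(self, small_cohort):
        _, counts, _, _, _ = small_cohort
        pooled = rs.pool_bulk(counts, counts.obs["patient"], mode="complete")
        assert pooled.profiles.to_numpy().sum() == np.asarray(counts.X).sum()

    def test_equal_mode_with_exact_totals_equals_complete(self):
        counts = make_counts([[2, 3, 1], [4, 1, 1]])
        smap = pd.Series("S1", index=counts.obs_names)
        complete = rs.pool_bulk(counts, smap, mode="complete")
        equal = rs.pool_bulk(counts, smap, mode="equal", d=6, seed=0)
        np.testing.assert_array_equal(equal.profiles, complete.profiles)

    def test_equal_mode_contribution_sums_to_d(self):
        rng = np.random.default_rng(0)
        counts = make_counts(rng.integers(0, 30, size=(8, 12)))
        smap = pd.Series([f"S{i % 2}" for i in range(8)], index=counts.obs_names)
        pooled = rs.pool_bulk(counts, smap, mode="equal", d=20, seed=1)
        for s in pooled.profiles.index:
            assert pooled.profiles.loc[s].sum() == 20 * pooled.cells_used[s]

    def test_equal_mode_restores_cell_share(self):
        """Deep cell (10,0) and shallow-skewed cell (0,1000): at d=10 both
        contribute 10, so gene 0 holds half the pool in expectation."""
        counts = make_counts([[10, 0], [0, 1000]])
        smap = pd.Series("S1", index=counts.obs_names)
        totals = np.zeros(2)
        for seed in range(200):
            pooled = rs.pool_bulk(counts, smap, mode="equal", d=10, seed=seed)
            totals += pooled.profiles.loc["S1"].to_numpy()
        share = totals[0] / totals.sum()
        assert share == pytest.approx(0.5, abs=1e-9)  # deterministic: cell totals fix it
        complete = rs.pool_bulk(counts, smap, mode="complete")
        complete_share = complete.profiles.loc["S1", "g0"] / complete.profiles.loc["S1"].sum()
        assert complete_share == pytest.approx(10 / 1010)

    def test_depth_bias_of_complete_pooling(self, small_cohort):
        """Resistant cells' transcript share under complete pooling sits below
        their cell share; equal pooling restores it."""
        _, counts, truth, _, _ = small_cohort
        resistant = (truth["latent_resistance"] > 0.5).fillna(False)
        cell_share = resistant.mean()
        totals = np.asarray(counts.X).sum(axis=1)
        transcript_share = totals[resistant.to_numpy()].sum() / totals.sum()
        assert transcript_share < cell_share
        d = int(totals.min())
        pooled = rs.pool_bulk(counts, pd.Series("S1", index=counts.obs_names),
                              mode="equal", d=d, seed=0)
        equal_share = (d * resistant.sum()) / (d * pooled.cells_used["S1"])
        assert equal_share == pytest.approx(cell_share, abs=0.01)

    def test_equal_mode_errors(self):
        counts = make_counts([[1, 1], [2, 0]])
        smap = pd.Series("S1", index=counts.obs_names)
        with pytest.raises(ValueError, match="positive"):
            rs.pool_bulk(counts, smap, mode="equal", d=0)
        with pytest.raises(ValueError, match="transcripts"):
            rs.pool_bulk(counts, smap, mode="equal", d=100)


class TestBulkModuleScore:
    def test_identical_profiles_equal_scores(self):
        prof = pd.DataFrame(
            [[5, 3, 2, 8, 1, 9], [5, 3, 2, 8, 1, 9]],
            index=["S1", "S2"], columns=[f"g{j}" for j in range(6)],
        )
        res = rs.GeneModule("resistance", "up", ("g0",))
        sens = rs.GeneModule("sensitivity", "down", ("g1",))
        out = rs.bulk_module_score(prof, res, sens, n_bins=1, n_ctrl=4, seed=0)
        assert out.loc["S1", "resistance_score"] == pytest.approx(out.loc["S2", "resistance_score"])

    def test_single_sample_rejected(self):
        prof = pd.DataFrame([[1, 2]], index=["S1"], columns=["g0", "g1"])
        res = rs.GeneModule("resistance", "up", ("g0",))
        sens = rs.GeneModule("sensitivity", "down", ("g1",))
        with pytest.raises(ValueError, match="2 samples"):
            rs.bulk_module_score(prof, res, sens)

    def test_pure_populations_separate(self):
        cfg = rs.SimConfig(
            n_patients=2, cells_per_patient=200, n_genes=500,
            n_sens_genes=80, n_res_genes=30, contaminant_fraction=0.0,
            resistance_beta_params=[(0.5, 20.0), (20.0, 0.5)], seed=13,
        )
        counts, truth, _, (res_mod, sens_mod) = rs.generate_cohort(cfg)
        pooled = rs.pool_bulk(counts, counts.obs["patient"], mode="equal", seed=0)
        out = rs.bulk_module_score(pooled, res_mod, sens_mod, n_bins=8, seed=0)
        # P01 is the near-pure sensitive sample
        assert out.loc["P01", "sensitivity_score"] > out.loc["P02", "sensitivity_score"]
        assert out.loc["P02", "resistance_score"] > out.loc["P01", "resistance_score"]
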