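"""Unit and property tests for the anti-correlation selection core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import anticorr as ac
from anticorr.core import AnticorConfig

from _oracle import oracle_feature_table


class TestDenseRank:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 5, 7], [1, 1, 2]),
            ([3, 1, 2], [3, 1, 2]),
            ([2, 2, 2], [1, 1, 1]),
            ([0.1, -4, 0.1, 9], [2, 1, 2, 3]),
        ],
    )
    def test_examples(self, values, expected):
        assert list(ac.dense_rank(np.array(values))) == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ac.dense_rank(np.array([]))

    @given(st.lists(st.integers(-50, 50), min_size=1, max_size=60))
    @settings(deadline=None)
    def test_max_rank_is_distinct_count(self, values):
        ranks = ac.dense_rank(np.array(values))
        assert ranks.max() == len(set(values))
        assert ranks.min() == 1
        assert set(ranks) == set(range(1, ranks.max() + 1))


class TestSelectCutoff:
    def test_brute_force_exceedance(self):
        b = np.array([-0.9, -0.8, -0.7, -0.6, -0.5, -0.4, -0.3, -0.2, -0.1, -0.05])
        c = ac.select_cutoff(b, fpr=0.2, side="negative")
        assert c == -0.8
        assert np.sum(b < c) == 1          # strictly beyond: 1 null value
        assert np.sum(b <= c) <= 2

    def test_fpr_one_returns_least_extreme(self):
        # boundary: floor(N*fpr) = N puts the cutoff at the least extreme value
        b = np.array([-0.9, -0.5, -0.1])
        assert ac.select_cutoff(b, fpr=1.0, side="negative") == -0.1

    def test_small_sample_falls_back_with_warning(self):
        b = np.array([-0.9, -0.5])
        with pytest.warns(UserWarning, match="most extreme"):
            assert ac.select_cutoff(b, fpr=0.001, side="negative") == -0.9

    def test_positive_side_mirrored(self):
        pos = np.array([0.9, 0.8, 0.3, 0.2, 0.1])
        assert ac.select_cutoff(pos, fpr=0.4, side="positive") == 0.8


class TestEstimateFdr:
    def test_direct_evaluation(self):
        table = pd.DataFrame({"t_i": [1000], "d_i": [30], "n_pos_partners": [0]})
        out = ac.estimate_fdr(table, fpr=0.001)
        assert out["fp_hat"].iloc[0] == pytest.approx(1.0)
        assert out["fdr_hat"].iloc[0] == pytest.approx(1 / 30)

    def test_no_discoveries_is_unselectable(self):
        table = pd.DataFrame({"t_i": [1000, 0], "d_i": [0, 0],
                              "n_pos_partners": [50, 0]})
        out = ac.estimate_fdr(table, fpr=0.001)
        assert (out["fdr_hat"] == 1.0).all()
        sel = ac.select_features(out, AnticorConfig())
        assert not sel["selected"].any()

    def test_clamped_to_one(self):
        table = pd.DataFrame({"t_i": [1000], "d_i": [1], "n_pos_partners": [0]})
        out = ac.estimate_fdr(table, fpr=0.5)
        assert out["fdr_hat"].iloc[0] == 1.0


class TestSelectFeatures:
    def test_module_filter_excludes_low_partner_gene(self):
        table = pd.DataFrame({
            "t_i": [100, 100], "d_i": [50, 50],
            "n_pos_partners": [3, 30],
        })
        out = ac.select_features(ac.estimate_fdr(table, 0.001), AnticorConfig())
        assert list(out["in_A"]) == [True, True]
        assert list(out["selected"]) == [False, True]

    def test_default_fdr_threshold_is_one_fifteenth(self):
        # published default 0.066 = 1/15 (a >15x discovery excess), as printed
        assert AnticorConfig().fdr_threshold == 0.066
        assert AnticorConfig().fdr_threshold == pytest.approx(1 / 15, abs=1e-3)

    def test_selected_is_conjunction(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "t_i": rng.integers(0, 200, 50),
            "d_i": rng.integers(0, 40, 50),
            "n_pos_partners": rng.integers(0, 30, 50),
        })
        table["d_i"] = np.minimum(table["d_i"], table["t_i"])
        out = ac.select_features(ac.estimate_fdr(table, 0.01), AnticorConfig())
        assert (out["selected"] == (out["in_A"] & out["in_M"])).all()


class TestNullBackground:
    def test_seeded_determinism(self, small_null):
        expr = np.log2(1.0 + small_null.counts)
        cfg = AnticorConfig(seed=9, null_sample_size=300)
        n1 = ac.build_null_background(expr, cfg)
        n2 = ac.build_null_background(expr, cfg)
        assert np.array_equal(n1.b_sorted, n2.b_sorted)
        assert n1.c_neg == n2.c_neg

    def test_sides_strictly_signed_and_cutoffs_members(self, small_null):
        expr = np.log2(1.0 + small_null.counts)
        null = ac.build_null_background(
            expr, AnticorConfig(seed=1, null_sample_size=300))
        assert (null.b_sorted < 0).all()
        assert (null.pos_sorted > 0).all()
        assert null.c_neg in null.b_sorted
        assert null.c_pos in null.pos_sorted

    def test_pair_count_matches_sample_size(self, small_null):
        expr = np.log2(1.0 + small_null.counts)
        null = ac.build_null_background(
            expr, AnticorConfig(seed=1, null_sample_size=100))
        m = len(null.sampled_gene_indices)
        # zeros are excluded from both sides; exact zeros are rare but legal
        assert null.b_sorted.size + null.pos_sorted.size <= m * (m - 1) // 2
        assert null.b_sorted.size + null.pos_sorted.size > 0.9 * m * (m - 1) // 2

    def test_two_seed_distribution_stability(self):
        """Negative null distribution is stable at sampling depth (KS < 0.01,
        threshold frozen from an independent pre-registered run)."""
        from scipy.stats import ks_2samp
        ds = ac.simulate_null_counts(300, 1500, seed=21)
        expr = np.log2(1.0 + ds.counts)
        n1 = ac.build_null_background(expr, AnticorConfig(seed=101))
        n2 = ac.build_null_background(expr, AnticorConfig(seed=202))
        assert ks_2samp(n1.b_sorted, n2.b_sorted).statistic < 0.01

    def test_too_few_genes_rejected(self):
        expr = np.ones((3, 20))
        with pytest.raises(ValueError, match="non-constant"):
            ac.build_null_background(expr, AnticorConfig(seed=0))


class TestSummarize:
    def test_symmetry_of_negative_tallies(self, small_null):
        expr = np.log2(1.0 + small_null.counts[:80])
        tab = ac.summarize_gene_correlations(expr, -0.3, 0.3, block_size=17)
        # sum of t_i counts each negative unordered pair twice
        assert tab["t_i"].sum() % 2 == 0

    def test_blocked_equals_unblocked(self, small_null):
        expr = np.log2(1.0 + small_null.counts[:60])
        a = ac.summarize_gene_correlations(expr, -0.25, 0.25, block_size=7)
        b = ac.summarize_gene_correlations(expr, -0.25, 0.25, block_size=1000)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_gene_contributes_to_neither_tally(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(10, 50))
        expr[1] = expr[0]  # perfect positive correlation pair
        tab = ac.summarize_gene_correlations(expr, -0.5, 0.99)
        # rho(0,1)=1 > 0: not in t or d; 1 > c_pos: counted as a positive partner
        assert tab.loc[tab.index[0], "n_pos_partners"] >= 1

    def test_constant_gene_flagged_and_zeroed(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(10, 50))
        expr[3] = 2.5
        tab = ac.summarize_gene_correlations(expr, -0.5, 0.5)
        row = tab.iloc[3]
        assert row["constant"]
        assert row["t_i"] == 0 and row["d_i"] == 0 and row["n_pos_partners"] == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_matrix_exact_match(self, seed):
        rng = np.random.default_rng(seed)
        expr = rng.lognormal(0.0, 1.0, size=(40, 80))
        orc = oracle_feature_table(expr, seed=seed)
        tab = ac.get_anti_cor_genes(expr, cfg=AnticorConfig(seed=seed))
        assert np.array_equal(orc["t"], tab["t_i"].to_numpy())
        assert np.array_equal(orc["d"], tab["d_i"].to_numpy())
        assert np.array_equal(orc["n_pos"], tab["n_pos_partners"].to_numpy())
        assert np.allclose(orc["fdr_hat"], tab["fdr_hat"].to_numpy())
        assert np.array_equal(orc["selected"], tab["selected"].to_numpy())


class TestEndToEnd:
    def test_null_data_selects_nothing(self, small_null):
        expr = np.log2(1.0 + small_null.counts)
        tab = ac.get_anti_cor_genes(expr, gene_ids=small_null.gene_ids,
                                    cfg=AnticorConfig(seed=4))
        assert tab["selected"].sum() == 0

    def test_planted_two_block_markers_selected(self, two_block_data):
        """On two mutually exclusive 30-gene marker blocks over NB noise the
        selection recovers exactly the 60 markers."""
        expr = np.log2(1.0 + two_block_data.counts)
        tab = ac.get_anti_cor_genes(expr, gene_ids=two_block_data.gene_ids,
                                    cfg=AnticorConfig(seed=4))
        assert np.array_equal(tab["selected"].to_numpy(),
                              two_block_data.true_deg)

    def test_cell_order_invariance(self, two_block_data):
        expr = np.log2(1.0 + two_block_data.counts)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.shape[1])
        t1 = ac.get_anti_cor_genes(expr, cfg=AnticorConfig(seed=4))
        t2 = ac.get_anti_cor_genes(expr[:, perm], cfg=AnticorConfig(seed=4))
        assert np.array_equal(t1["selected"].to_numpy(),
                              t2["selected"].to_numpy())

    def test_monotone_transform_invariance(self, two_block_data):
        """Spearman-based selection is invariant to strictly monotone
        per-gene transforms of the expression values."""
        expr = np.log2(1.0 + two_block_data.counts.astype(float))
        t1 = ac.get_anti_cor_genes(expr, cfg=AnticorConfig(seed=4))
        t2 = ac.get_anti_cor_genes(np.expm1(expr) * 3 + 1,
                                   cfg=AnticorConfig(seed=4))
        pd.testing.assert_frame_equal(t1, t2)

    def test_threshold_monotonicity(self, two_block_data):
        """Lowering fdr_threshold or raising min_positive_partners never
        enlarges the selected set."""
        expr = np.log2(1.0 + two_block_data.counts)
        null = ac.build_null_background(expr, AnticorConfig(seed=4))
        base = ac.estimate_fdr(
            ac.summarize_gene_correlations(expr, null.c_neg, null.c_pos),
            0.001)
        prev = None
        for fdr in (0.5, 0.25, 0.066, 0.01):
            sel = set(np.flatnonzero(ac.select_features(
                base, AnticorConfig(fdr_threshold=fdr))["selected"]))
            if prev is not None:
                assert sel <= prev
            prev = sel
        prev = None
        for mpp in (5, 10, 20):
            sel = set(np.flatnonzero(ac.select_features(
                base, AnticorConfig(min_positive_partners=mpp))["selected"]))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_pre_removal_empty_list_is_identity(self, small_null):
        expr = np.log2(1.0 + small_null.counts[:100])
        t1 = ac.get_anti_cor_genes(expr, cfg=AnticorConfig(seed=2))
        t2 = ac.get_anti_cor_genes(
            expr, cfg=AnticorConfig(seed=2, pre_remove_genes=[]))
        pd.testing.assert_frame_equal(t1, t2)

    def test_pre_removal_default_patterns(self):
        rng = np.random.default_rng(1)
        expr = rng.lognormal(0, 1, size=(30, 60))
        ids = [f"GENE{i}" for i in range(27)] + ["RPL7", "MT-CO1", "HBB"]
        tab = ac.get_anti_cor_genes(
            expr, gene_ids=ids,
            cfg=AnticorConfig(seed=2, pre_remove_genes="default"))
        removed = tab.loc[["RPL7", "MT-CO1", "HBB"]]
        assert (removed["t_i"] == 0).all()
        assert not removed["selected"].any()
        assert list(tab.index) == ids  # full index preserved

    def test_fpr_calibration_on_null(self):
        """Realized discovery fraction beyond c_neg on null data is within 3
        binomial SEs of the configured FPR."""
        ds = ac.simulate_null_counts(300, 1500, seed=21)
        expr = np.log2(1.0 + ds.counts)
        for fpr in (0.01, 0.001):
            cfg = AnticorConfig(fpr=fpr, seed=5)
            null = ac.build_null_background(expr, cfg)
            tab = ac.summarize_gene_correlations(expr, null.c_neg, null.c_pos)
            n = tab["t_i"].sum()
            frac = tab["d_i"].sum() / n
            se = np.sqrt(fpr * (1 - fpr) / n)
            assert abs(frac - fpr) < 3 * se


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"fpr": 0.0}, {"fpr": 1.0}, {"fdr_threshold": 1.5},
        {"null_sample_size": 1}, {"block_size": 0},
    ])
    def test_bad_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnticorConfig(**kwargs)
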