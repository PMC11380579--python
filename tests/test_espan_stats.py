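"""Tests for the core bias statistics: normalization, bias, metaprofiles,
arm summaries, rank-sum tests, density comparisons and heatmaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import espan
from espan import espan_stats
from espan.espan_stats import (
    BiasProfile,
    NormalizedDensity,
    arm_bias_summary,
    compare_conditions,
    compute_bias,
    heatmap_matrix,
    normalize_density,
    origin_metaprofile,
    strand_density_summary,
    wilcoxon_arm_test,
)


def make_bias(values, bin_width=500, chrom="chrSim"):
    values = np.asarray(values, dtype=float)
    return BiasProfile(chrom=chrom, chrom_length=len(values) * bin_width,
                       bin_width=bin_width, bias=values, mask=~np.isnan(values))


def make_density(watson, crick, mask=None, bin_width=500):
    watson = np.asarray(watson, dtype=float)
    crick = np.asarray(crick, dtype=float)
    if mask is None:
        mask = np.ones(len(watson), dtype=bool)
    return NormalizedDensity(chrom="chrSim", chrom_length=len(watson) * bin_width,
                             bin_width=bin_width, dens_watson=watson, dens_crick=crick,
                             mask=np.asarray(mask, dtype=bool))


class TestNormalizeDensity:
    def test_hand_ratio_without_pseudocount(self, make_coverage):
        espan_cov = make_coverage([30], [30], library_size=100)
        brdu_cov = make_coverage([20], [40], library_size=100)
        dens = normalize_density(espan_cov, brdu_cov, pseudocount=0.0, min_brdu=0)
        assert dens.dens_watson[0] == pytest.approx(1.5)
        assert dens.dens_crick[0] == pytest.approx(0.75)

    def test_low_brdu_bin_masked(self, make_coverage):
        espan_cov = make_coverage([10, 10], [10, 10])
        brdu_cov = make_coverage([10, 0], [10, 0])
        dens = normalize_density(espan_cov, brdu_cov, min_brdu=5)
        assert dens.mask.tolist() == [True, False]

    def test_cpm_scale_invariance(self, make_coverage):
        e1 = make_coverage([30, 10], [20, 5], library_size=100)
        e2 = make_coverage([60, 20], [40, 10], library_size=200)
        b = make_coverage([20, 20], [20, 20], library_size=100)
        d1 = normalize_density(e1, b, pseudocount=0.5, min_brdu=0)
        d2 = normalize_density(e2, b, pseudocount=0.5, min_brdu=0)
        np.testing.assert_allclose(d1.dens_watson, d2.dens_watson)
        np.testing.assert_allclose(d1.dens_crick, d2.dens_crick)

    def test_region_filter_masks_outside(self, make_coverage):
        from espan.enrich_call import EnrichedRegion

        e = make_coverage([10] * 10, [10] * 10)
        b = make_coverage([10] * 10, [10] * 10)
        regions = [EnrichedRegion("chrSim", 1000, 2000, 2.0, 5.0)]
        dens = normalize_density(e, b, min_brdu=0, regions=regions)
        assert dens.mask.tolist() == [False, False, True, True] + [False] * 6

    def test_mismatched_binning_rejected(self, make_coverage):
        with pytest.raises(ValueError, match="binning"):
            normalize_density(make_coverage([1], [1], bin_width=500),
                              make_coverage([1], [1], bin_width=200))


class TestComputeBias:
    def test_symmetry_and_hand_value(self, make_coverage):
        # hand oracle: log2((30/20)/(10/20)) = log2(3) = 1.58496
        e = make_coverage([30], [10], library_size=100)
        b = make_coverage([20], [20], library_size=100)
        bias = compute_bias(normalize_density(e, b, pseudocount=0.0, min_brdu=0))
        assert bias.bias[0] == pytest.approx(np.log2(3.0), abs=1e-9)

        eq = compute_bias(make_density([2.0], [2.0]))
        assert eq.bias[0] == pytest.approx(0.0)

    def test_antisymmetric_under_strand_swap(self):
        rng = np.random.default_rng(1)
        dens = make_density(rng.uniform(0.1, 5, 50), rng.uniform(0.1, 5, 50))
        fwd = compute_bias(dens)
        rev = compute_bias(dens.swapped())
        np.testing.assert_allclose(fwd.bias, -rev.bias)

    def test_mask_propagated_as_nan(self):
        dens = make_density([1, 2], [1, 1], mask=[True, False])
        bias = compute_bias(dens)
        assert np.isnan(bias.bias[1]) and not np.isnan(bias.bias[0])


class TestMetaprofile:
    def test_replicate_ci_hand_computed(self):
        """Replicates 0.5 and 0.7 at every position: mean 0.6, CI [0.4, 0.8]."""
        reps = [make_bias([0.5] * 40), make_bias([0.7] * 40)]
        mp = origin_metaprofile(reps, np.array([10_000]), window_bp=5_000)
        np.testing.assert_allclose(mp.mean, 0.6)
        np.testing.assert_allclose(mp.ci_low, 0.4, atol=1e-12)
        np.testing.assert_allclose(mp.ci_high, 0.8, atol=1e-12)
        assert mp.n_replicates == 2

    def test_single_replicate_ci_undefined(self):
        mp = origin_metaprofile([make_bias([0.5] * 40)], np.array([10_000]), 5_000)
        np.testing.assert_allclose(mp.mean, 0.5)
        assert np.isnan(mp.se).all() and np.isnan(mp.ci_low).all()

    def test_fully_masked_position_flagged_not_fabricated(self):
        vals = np.full(40, 0.3)
        vals[25] = np.nan
        mp = origin_metaprofile([make_bias(vals)] * 2, np.array([10_000]), 5_000)
        col = 25 - (10_000 // 500 - 5_000 // 500)  # origin bin 20, window starts at bin 10
        assert np.isnan(mp.mean[col])
        assert (mp.n_origins[:, col] == 0).all()

    def test_window_must_tile_bins(self):
        with pytest.raises(ValueError, match="multiple"):
            origin_metaprofile([make_bias([0.0] * 40)], np.array([10_000]), 1_234)

    def test_two_replicate_ci_coverage_matches_theory(self):
        """For two iid mean-zero replicate profiles the mean +- 2 SE band covers
        zero at P(|Cauchy| <= 2) ~= 70.5% of positions, not 95%."""
        rng = np.random.default_rng(0)
        n = 4000
        reps = [make_bias(rng.normal(0, 0.3, n)), make_bias(rng.normal(0, 0.3, n))]
        mp = origin_metaprofile(reps, np.array([n * 500 // 2]), window_bp=n * 500 // 2)
        cover = np.nanmean((mp.ci_low <= 0) & (mp.ci_high >= 0))
        expected = 2 / np.pi * np.arctan(2)
        assert abs(cover - expected) < 0.04


class TestArmSummary:
    def test_antisymmetric_arms_give_score(self):
        vals = np.concatenate([np.full(10, -0.8), np.full(10, 0.8)])
        df = arm_bias_summary(make_bias(vals), np.array([5_000]), window_bp=5_000)
        assert df.loc[0, "left_mean_bias"] == pytest.approx(-0.8)
        assert df.loc[0, "right_mean_bias"] == pytest.approx(0.8)
        assert df.loc[0, "leading_bias_score"] == pytest.approx(0.8)

    def test_uniform_offset_cancels(self):
        df = arm_bias_summary(make_bias([0.37] * 20), np.array([5_000]), 5_000)
        assert df.loc[0, "leading_bias_score"] == pytest.approx(0.0)

    def test_score_negates_with_bias(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 20)
        a = arm_bias_summary(make_bias(vals), np.array([5_000]), 5_000)
        b = arm_bias_summary(make_bias(-vals), np.array([5_000]), 5_000)
        assert a.loc[0, "leading_bias_score"] == pytest.approx(
            -b.loc[0, "leading_bias_score"])

    def test_all_masked_arm_excludes_origin(self):
        vals = np.concatenate([np.full(10, np.nan), np.full(10, 0.5)])
        df = arm_bias_summary(make_bias(vals), np.array([5_000]), 5_000)
        assert len(df) == 0
        assert df.attrs["n_excluded"] == 1

    def test_simulated_p_lead_sign_recovery(self):
        """p_lead 0.8 drives a positive mean score; 0.2 a negative one."""
        scores = {}
        for p_lead in (0.2, 0.8):
            c = espan.default_config(n_origins=8, p_lead=p_lead, depth=300_000, seed=4)
            lay = espan.build_layout(c)
            st = espan.simulate_replication(lay, c)
            e = espan.bin_coverage(espan.generate_reads(st, "espan_parental", seed=4),
                                   lay.genome_length, 500)
            b = espan.bin_coverage(espan.generate_reads(st, "mnase_brdu_ip", seed=4),
                                   lay.genome_length, 500)
            bias = compute_bias(normalize_density(e, b))
            scores[p_lead] = arm_bias_summary(bias, lay.origins, 5_000)[
                "leading_bias_score"].mean()
        assert scores[0.8] > 0 > scores[0.2]


class TestWilcoxon:
    def test_exact_enumeration_examples(self):
        _, p = wilcoxon_arm_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        _, p = wilcoxon_arm_test([1, 4], [2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for n, m in [(3, 4), (5, 5), (6, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(0.5, size=m)
            u, p = wilcoxon_arm_test(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n10(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        y = rng.normal(0.8, size=10)
        _, p = wilcoxon_arm_test(x, y)  # n + m > 12: asymptotic path
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert abs(p - ref.pvalue) < 0.01

    def test_degenerate_identical_values(self):
        _, p = wilcoxon_arm_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_arm_test([], [1.0])

    def test_exact_null_distribution_symmetry(self):
        """Enumerated U null is symmetric about nm/2 (here n=m=3, U in [0, 9])."""
        us = [sum(r) - 6 for r in itertools.combinations(range(1, 7), 3)]
        assert sorted(us) == sorted(9 - u for u in us)


class TestDensitySummary:
    def test_fork_geometry_mapping(self):
        dens = make_density([0.0] * 20, [0.0] * 20, mask=[False] * 20)
        # one unmasked bin at origin+500 with D(W)=2, D(C)=1
        dens.dens_watson[11], dens.dens_crick[11] = 2.0, 1.0
        dens.mask[11] = True
        df = strand_density_summary([dens], np.array([5_000]), window_bp=2_500)
        assert df.loc[0, "leading_density"] == pytest.approx(2.0)
        assert df.loc[0, "lagging_density"] == pytest.approx(1.0)

    def test_mirror_bin_swaps_strands(self):
        dens = make_density([0.0] * 20, [0.0] * 20, mask=[False] * 20)
        dens.dens_watson[9], dens.dens_crick[9] = 2.0, 1.0  # origin - 500
        dens.mask[9] = True
        df = strand_density_summary([dens], np.array([5_000]), window_bp=2_500)
        assert df.loc[0, "leading_density"] == pytest.approx(1.0)
        assert df.loc[0, "lagging_density"] == pytest.approx(2.0)

    def test_replicates_averaged_per_origin(self):
        d1 = make_density([1.0] * 20, [1.0] * 20)
        d2 = make_density([3.0] * 20, [3.0] * 20)
        df = strand_density_summary([d1, d2], np.array([5_000]), 2_500)
        assert df.loc[0, "leading_density"] == pytest.approx(2.0)

    def test_symmetric_simulation_paired_difference_near_zero(self):
        c = espan.default_config(n_origins=10, p_lead=0.5, depth=500_000, seed=6)
        lay = espan.build_layout(c)
        dens = []
        for rep in range(2):
            st = espan.simulate_replication(lay, c, seed=[6, rep])
            e = espan.bin_coverage(
                espan.generate_reads(st, "espan_parental", seed=6, replicate=rep),
                lay.genome_length, 500)
            b = espan.bin_coverage(
                espan.generate_reads(st, "mnase_brdu_ip", seed=6, replicate=rep),
                lay.genome_length, 500)
            dens.append(normalize_density(e, b))
        df = strand_density_summary(dens, lay.origins, 2_500)
        diff = df["leading_density"] - df["lagging_density"]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 0.02


class TestCompareConditions:
    def frame(self, leading, lagging):
        return pd.DataFrame({"leading_density": leading, "lagging_density": lagging})

    def test_exact_scaling_gives_minus_35(self):
        wt = self.frame([1.0, 1.2, 0.8, 1.1], [0.9, 1.0, 1.3, 0.7])
        mut = self.frame(np.array(wt["leading_density"]) * 0.65,
                         np.array(wt["lagging_density"]) * 0.65)
        comp = compare_conditions(wt, mut)
        assert comp["percent_change"].tolist() == pytest.approx([-35.0, -35.0])

    def test_identical_conditions_null(self):
        wt = self.frame([1.0, 1.2, 0.8, 1.1], [1.0, 1.2, 0.8, 1.1])
        comp = compare_conditions(wt, wt)
        assert comp["percent_change"].tolist() == pytest.approx([0.0, 0.0])
        assert (comp["p_value"] > 0.99).all()

    def test_welch_matches_hand_formula(self):
        wt_v = np.array([1.0, 1.2, 0.8, 1.1])
        mut_v = np.array([0.7, 0.6, 0.8, 0.5])
        comp = compare_conditions(self.frame(wt_v, wt_v), self.frame(mut_v, mut_v))
        # independent Welch computation
        va, vb = wt_v.var(ddof=1) / 4, mut_v.var(ddof=1) / 4
        t_hand = (mut_v.mean() - wt_v.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert comp.loc[0, "t_statistic"] == pytest.approx(t_hand)
        assert comp.loc[0, "p_value"] == pytest.approx(p_hand)

    def test_zero_wildtype_mean_rejected(self):
        with pytest.raises(ValueError, match="percent change undefined"):
            compare_conditions(self.frame([0.0, 0.0], [1, 1]), self.frame([1, 1], [1, 1]))


class TestHeatmap:
    def test_shape_and_row_means(self):
        vals = np.arange(20, dtype=float)
        hm = heatmap_matrix(make_bias(vals), np.array([2_000, 7_000]), window_bp=1_000)
        assert hm.shape == (2, 4)
        arm = arm_bias_summary(make_bias(vals), np.array([2_000, 7_000]), 1_000)
        row_means = hm.mean(axis=1).to_numpy()
        expect = ((arm["left_mean_bias"] + arm["right_mean_bias"]) / 2).to_numpy()
        np.testing.assert_allclose(row_means, expect)

    def test_score_sorting_descending(self):
        vals = np.zeros(20)
        vals[14:16] = 1.0  # second origin right arm high -> big score
        hm = heatmap_matrix(make_bias(vals), np.array([2_000, 7_000]), 1_000,
                            sort_mode="score")
        assert hm.index.tolist() == ["origin_1", "origin_0"]

    def test_invalid_sort_mode(self):
        with pytest.raises(ValueError, match="sort_mode"):
            heatmap_matrix(make_bias(np.zeros(20)), np.array([2_000]), 1_000, "banana")


class TestEndToEndAntisymmetry:
    def test_strand_relabel_negates_bias_and_swaps_densities(self):
        """Relabeling Watson<->Crick in all inputs negates every bias value and
        leading-bias score and swaps leading/lagging densities (exact)."""
        c = espan.default_config(n_origins=5, depth=200_000, seed=8)
        lay = espan.build_layout(c)
        st = espan.simulate_replication(lay, c)
        e = espan.bin_coverage(espan.generate_reads(st, "espan_parental", seed=8),
                               lay.genome_length, 500)
        b = espan.bin_coverage(espan.generate_reads(st, "mnase_brdu_ip", seed=8),
                               lay.genome_length, 500)
        dens = normalize_density(e, b)
        sw = dens.swapped()
        bias_f, bias_r = compute_bias(dens), compute_bias(sw)
        np.testing.assert_allclose(bias_f.bias, -bias_r.bias, equal_nan=True)
        a_f = arm_bias_summary(bias_f, lay.origins, 5_000)
        a_r = arm_bias_summary(bias_r, lay.origins, 5_000)
        np.testing.assert_allclose(a_f["leading_bias_score"], -a_r["leading_bias_score"])
        d_f = strand_density_summary([dens], lay.origins, 2_500)
        d_r = strand_density_summary([sw], lay.origins, 2_500)
        np.testing.assert_allclose(d_f["leading_density"], d_r["lagging_density"])
        np.testing.assert_allclose(d_f["lagging_density"], d_r["leading_density"])


def test_new_histone_bias_compensates_parental():
    """With full new-histone fill-in, the new-mark bias has the opposite sign to
    the parental bias whenever transfer is asymmetric."""
    c = espan.default_config(n_origins=8, p_lead=0.8, new_fill=1.0, depth=400_000, seed=9)
    lay = espan.build_layout(c)
    st = espan.simulate_replication(lay, c)
    b = espan.bin_coverage(espan.generate_reads(st, "mnase_brdu_ip", seed=9),
                           lay.genome_length, 500)
    scores = {}
    for mark in ("parental", "new"):
        e = espan.bin_coverage(espan.generate_reads(st, f"espan_{mark}", seed=9),
                               lay.genome_length, 500)
        bias = compute_bias(normalize_density(e, b))
        scores[mark] = arm_bias_summary(bias, lay.origins, 5_000)[
            "leading_bias_score"].mean()
    assert scores["parental"] > 0 > scores["new"]


class TestSingleReplicateSEMode:
    def test_across_origin_se_substituted(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 40)
        prof = make_bias(vals)
        mp = origin_metaprofile([prof], np.array([5_000, 15_000]), window_bp=2_500,
                                single_rep_se="origins")
        assert np.isfinite(mp.se).any()
        # two origins per position: SE = |a - b| / 2 at each position
        col = 2
        a = vals[10 - 5 + col]
        b = vals[30 - 5 + col]
        assert mp.se[col] == pytest.approx(abs(a - b) / 2)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="single_rep_se"):
            origin_metaprofile([make_bias(np.zeros(40))], np.array([5_000]), 2_500,
                               single_rep_se="banana")


def test_bias_at_dyads_maps_bins_and_masks():
    from espan.enrich_call import NucleosomeCall
    from espan.espan_stats import bias_at_dyads

    vals = np.array([0.1, np.nan, 0.3, 0.4])
    bias = make_bias(vals)
    calls = [NucleosomeCall("chrSim", 600, 5.0),   # bin 1 (masked)
             NucleosomeCall("chrSim", 1200, 2.0)]  # bin 2
    df = bias_at_dyads(bias, calls)
    assert np.isnan(df.loc[0, "bias"])
    assert df.loc[1, "bias"] == pytest.approx(0.3)
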