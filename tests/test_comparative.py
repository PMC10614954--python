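"""Housekeeping normalization, log2FC, gene grouping, XCU statistics,
GGACH motifs, and the disease-transfer protocol."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosscell import (adjust_pvalues, assign_gene_groups, compare_motif_shift,
                       count_ggach, disease_log2fc, housekeeping_normalize,
                       per_cell_log2fc, transfer_eval, xcu_group_tests)
# aliased so pytest does not collect the library function as a test
from crosscell import test_group_shift as wilcoxon_group_shift


class TestHousekeepingNormalize:
    def test_basic_example(self):
        profiles = np.array([[2.0], [4.0]])   # hk gene then other gene
        out, keep = housekeeping_normalize(profiles, [True, False])
        np.testing.assert_allclose(out.ravel(), [1.0, 2.0])
        assert keep.all()

    def test_global_scalar_removed(self):
        rng = np.random.default_rng(0)
        prof = rng.random((5, 3)) + 0.1
        scaled = prof * np.array([1.0, 7.0, 0.3])
        hk = np.array([True, True, False, False, False])
        a, _ = housekeeping_normalize(prof, hk)
        b, _ = housekeeping_normalize(scaled, hk)
        np.testing.assert_allclose(a, b)

    def test_all_genes_equals_depth_normalization(self):
        prof = np.array([[2.0, 1.0], [6.0, 3.0]])
        out, _ = housekeeping_normalize(prof, [True, True])
        np.testing.assert_allclose(out.sum(axis=0), 1.0)

    def test_zero_hk_cells_excluded(self, caplog):
        prof = np.array([[1.0, 0.0], [1.0, 1.0]])
        out, keep = housekeeping_normalize(prof, [True, False])
        assert keep.tolist() == [True, False]
        assert out.shape == (2, 1)

    def test_no_hk_genes_raises(self):
        with pytest.raises(ValueError):
            housekeeping_normalize(np.ones((2, 2)), [False, False])


class TestPerCellLog2FC:
    def test_doubling_gives_one(self):
        a = np.full((4, 3), 2.0)
        b = np.full((4, 3), 1.0)
        np.testing.assert_allclose(per_cell_log2fc(a, b, eps=0.0), 1.0)

    def test_identity_gives_zero(self):
        a = np.random.default_rng(0).random((5, 4)) + 0.5
        np.testing.assert_allclose(per_cell_log2fc(a, a.copy()), 0.0)

    def test_median_over_cells(self):
        a = np.array([[1.0, 2.0, 100.0]])
        b = np.ones((1, 3))
        assert per_cell_log2fc(a, b, eps=0.0)[0] == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 5)) + 0.1, rng.random((6, 5)) + 0.1
        np.testing.assert_allclose(per_cell_log2fc(a, b), -per_cell_log2fc(b, a),
                                   atol=1e-12)

    def test_mismatched_cells_raise(self):
        with pytest.raises(ValueError):
            per_cell_log2fc(np.ones((2, 3)), np.ones((2, 4)))


class TestGeneGroups:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom_mouse", "chrom_opossum",
                                           "chrom_chicken"])

    def test_canonical_assignments(self):
        df = self._frame([("chrX", "chr4", "chr1"),   # XAR
                          ("chrX", "chrX", "chr4"),   # XCR
                          ("chr2", "chr1", "chr3"),   # autosomal
                          ("chr2", "chrX", "chr3"),   # inconsistent -> excluded
                          ("chrX", "chr4", None)])    # missing -> excluded
        got = assign_gene_groups(df).tolist()
        assert got == ["XAR", "XCR", "autosomal", "excluded", "excluded"]

    def test_pure_function_of_rows(self):
        df = self._frame([("chrX", "chr4", "chr1"), ("chr2", "chr1", "chr3"),
                          ("chrX", "chrX", "chr4")])
        perm = df.iloc[[2, 0, 1]].reset_index(drop=True)
        got = assign_gene_groups(df)
        got_perm = assign_gene_groups(perm)
        assert got.iloc[[2, 0, 1]].tolist() == got_perm.tolist()


class TestWilcoxon:
    def test_all_values_above_null_exact_p(self):
        # 20 zeros against null -1, alternative greater: one-sided p = 2^-20
        p, tied = wilcoxon_group_shift(np.zeros(20), -1.0, "greater")
        assert not tied
        assert p == pytest.approx(2.0 ** -20, rel=1e-6)

    def test_symmetric_values_give_half(self):
        vals = np.concatenate([np.arange(1, 11), -np.arange(1, 11)])
        p, _ = wilcoxon_group_shift(vals, 0.0, "greater")
        assert 0.3 < p < 0.7

    def test_all_tied_flagged(self):
        p, tied = wilcoxon_group_shift(np.full(10, -1.0), -1.0, "greater")
        assert p == 1.0 and tied

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sign_enumeration_oracle(self, seed):
        """Exact p equals brute-force enumeration over all 2^n sign patterns."""
        rng = np.random.default_rng(seed)
        vals = np.round(rng.normal(0.3, 1.0, size=8), 3)
        while len(np.unique(np.abs(vals))) < 8 or (vals == 0).any():
            vals = np.round(rng.normal(0.3, 1.0, size=8), 3)
        p, _ = wilcoxon_group_shift(vals, 0.0, "greater")
        ranks = stats.rankdata(np.abs(vals))
        w_obs = ranks[vals > 0].sum()
        count = sum(ranks[np.array(signs, dtype=bool)].sum() >= w_obs
                    for signs in product([0, 1], repeat=8))
        assert p == pytest.approx(count / 2**8, rel=1e-12)

    def test_type_i_error_near_alpha(self):
        """Normal samples centred at the null reject in ~5% of simulations."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            vals = rng.normal(-1.0, 1.0, size=60)
            p, _ = wilcoxon_group_shift(vals, -1.0, "greater")
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_invalid_alternative_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_group_shift(np.ones(5), 0.0, "two-sided")


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.04]), [0.04])

    def test_hand_computed_three_values(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_pvalues([1.0, 1.0]), [1.0, 1.0])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = adjust_pvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


class TestXcuGroupTests:
    def test_grouped_pipeline_with_bh(self):
        rng = np.random.default_rng(3)
        fc = np.concatenate([rng.normal(0.0, 0.3, 50),    # XAR: well above -1
                             rng.normal(-1.0, 0.3, 50)])  # XCR: at the null
        groups = pd.Series(["XAR"] * 50 + ["XCR"] * 50)
        out = xcu_group_tests(fc, groups, null_median=-1.0, alternative="greater")
        assert list(out["group"]) == ["XAR", "XCR"]
        assert out.loc[0, "p"] < 1e-6 and out.loc[1, "p"] > 0.05
        assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestGgach:
    @pytest.mark.parametrize("seq,count", [
        ("GGACA", 1), ("GGACG", 0), ("GGACAGGACT", 2),
        ("GGACU", 1), ("GGGACA", 1), ("GGACGGACT", 1)])
    def test_counts(self, seq, count):
        assert count_ggach(seq)[0] == count

    def test_overlapping_occurrences_counted(self):
        # GGACC contains GGAC[C]; the following GGACT overlaps its start
        assert count_ggach("GGACCGGACT")[0] == 2

    def test_per_kb_frequency(self):
        n, freq = count_ggach("GGACA" * 200)   # 1000 bp, 200 motifs
        assert n == 200 and freq == pytest.approx(200.0)

    def test_empty_and_bad_alphabet_raise(self):
        with pytest.raises(ValueError):
            count_ggach("")
        with pytest.raises(ValueError):
            count_ggach("GGACZ")


class TestMotifShift:
    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        delta_src = rng.normal(size=200)
        f1 = np.concatenate([delta_src[:100], delta_src[100:]])
        groups = pd.Series(["XCR"] * 100 + ["autosomal"] * 100)
        out = compare_motif_shift(f1, np.zeros(200), groups, x_groups=("XCR",))
        assert 0.2 < out.loc[0, "p"] < 0.8

    def test_negative_shift_detected(self):
        rng = np.random.default_rng(1)
        detections = 0
        for trial in range(50):
            d_x = rng.normal(-1.0, 1.0, 100)
            d_auto = rng.normal(0.0, 1.0, 100)
            groups = pd.Series(["XAR"] * 100 + ["autosomal"] * 100)
            out = compare_motif_shift(np.concatenate([d_x, d_auto]),
                                      np.zeros(200), groups, x_groups=("XAR",))
            detections += out.loc[0, "p"] < 0.01
        assert detections >= 48   # >= 95% power with margin

    def test_matches_reference_ranksum_on_fixed_instance(self):
        rng = np.random.default_rng(7)
        d_x, d_auto = rng.normal(size=10), rng.normal(size=10)
        groups = pd.Series(["XCR"] * 10 + ["autosomal"] * 10)
        out = compare_motif_shift(np.concatenate([d_x, d_auto]), np.zeros(20),
                                  groups, x_groups=("XCR",))
        want = stats.mannwhitneyu(d_x, d_auto, alternative="less")[1]
        assert out.loc[0, "p"] == pytest.approx(want)

    def test_small_group_raises(self):
        groups = pd.Series(["XCR"] * 3 + ["autosomal"] * 10)
        with pytest.raises(ValueError):
            compare_motif_shift(np.zeros(13), np.zeros(13), groups, x_groups=("XCR",))


class TestDiseaseTransfer:
    def test_log2fc_examples(self):
        assert disease_log2fc([19.0], [9.0])[0] == pytest.approx(1.0)
        assert disease_log2fc([5.0], [5.0])[0] == 0.0
        assert disease_log2fc([0.0], [0.0])[0] == 0.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            disease_log2fc([], [1.0])

    def test_transfer_eval_perfect_and_null(self):
        rng = np.random.default_rng(4)
        obs = {"ct1": rng.normal(size=500)}
        perm = {"ct1": rng.permutation(obs["ct1"])}
        out = transfer_eval(obs, obs, perm)
        assert out.loc[0, "prediction_cor"] == pytest.approx(1.0)
        assert abs(out.loc[0, "baseline_cor"]) < 0.15

    def test_zero_variance_observed_raises(self):
        with pytest.raises(ValueError):
            transfer_eval({"a": np.ones(3)}, {"a": np.ones(3)}, {"a": np.ones(3)})
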