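"""RPKM binning, log2 enrichment, metaprofiles, expression integration."""
import numpy as np
import pandas as pd
import pytest

from conftest import track_from
from methwave.chromatin import (EnrichParams, EnrichmentTrack,
                                ExpressionGroups, bin_rpkm,
                                delta_delta_regression,
                                expression_methylation_matrix,
                                log2_enrichment, metaprofile_anchor,
                                metaprofile_scaled)
from methwave.types import GeneModel, GenomicInterval

SIZES = {"chr1": 10_000}


def reads_at(starts, chrom="chr1", length=50):
    return [GenomicInterval(chrom, s, s + length, strand="+") for s in starts]


class TestBinRpkm:
    def test_rpkm_formula_1kb(self):
        track = bin_rpkm(reads_at([100] * 10), SIZES, total_reads=1_000_000)
        assert track.values["chr1"][0] == pytest.approx(10.0)

    def test_rpkm_formula_2kb(self):
        track = bin_rpkm(reads_at([100] * 20), SIZES,
                         EnrichParams(bin_bp=2000), total_reads=2_000_000)
        assert track.values["chr1"][0] == pytest.approx(5.0)

    def test_counts_match_bruteforce_and_conserve(self, rng):
        starts = rng.integers(0, 9_000, 500)
        track = bin_rpkm(reads_at(starts), SIZES)
        # back out counts from RPKM
        counts = track.values["chr1"] * (1.0 * (500 / 1e6))
        expect = np.bincount(starts // 1000, minlength=10)
        assert np.allclose(counts, expect)
        assert counts.sum() == 500

    def test_five_prime_end_assignment(self):
        minus = [GenomicInterval("chr1", 980, 1030, strand="-")]
        track = bin_rpkm(minus, SIZES)
        assert track.values["chr1"][1] > 0 and track.values["chr1"][0] == 0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            bin_rpkm([], SIZES)


class TestLog2Enrichment:
    def test_chip_vs_itself_is_zero(self, rng):
        track = bin_rpkm(reads_at(rng.integers(0, 9_000, 200)), SIZES)
        ratio = log2_enrichment(track, track)
        assert np.allclose(ratio.values["chr1"], 0.0)

    def test_fourfold_with_tiny_pseudocount(self):
        chip = bin_rpkm(reads_at([100] * 8), SIZES, total_reads=1_000_000)
        inp = bin_rpkm(reads_at([100] * 2), SIZES, total_reads=1_000_000)
        ratio = log2_enrichment(chip, inp, EnrichParams(pseudocount_rpkm=1e-9))
        assert ratio.values["chr1"][0] == pytest.approx(2.0, abs=1e-6)

    def test_empty_bins_defined(self):
        chip = bin_rpkm(reads_at([100]), SIZES)
        inp = bin_rpkm(reads_at([5_100]), SIZES)
        ratio = log2_enrichment(chip, inp)
        assert np.isfinite(ratio.values["chr1"]).all()
        assert ratio.values["chr1"][8] == 0.0  # empty in both

    def test_mismatched_bins_rejected(self):
        a = bin_rpkm(reads_at([0]), SIZES)
        b = bin_rpkm(reads_at([0]), SIZES, EnrichParams(bin_bp=500))
        with pytest.raises(ValueError, match="mismatch"):
            log2_enrichment(a, b)


class TestMetaprofileAnchor:
    def test_constant_track_flat_profile(self):
        track = EnrichmentTrack(1000, SIZES,
                                {"chr1": np.full(10, 3.5)})
        prof = metaprofile_anchor(track, [("chr1", 5_000, "+")],
                                  flank_bp=2_000, n_bins=8)
        assert np.allclose(prof.column_means, 3.5)

    def test_step_function_reproduced(self):
        values = np.r_[np.zeros(5), np.ones(5)]
        track = EnrichmentTrack(1000, SIZES, {"chr1": values})
        prof = metaprofile_anchor(track, [("chr1", 5_000, "+")],
                                  flank_bp=2_000, n_bins=4)
        assert prof.column_means.tolist() == [0, 0, 1, 1]

    def test_minus_strand_mirrors(self):
        values = np.arange(10, dtype=float)
        track = EnrichmentTrack(1000, SIZES, {"chr1": values})
        plus = metaprofile_anchor(track, [("chr1", 5_000, "+")], 2_000, 4)
        minus = metaprofile_anchor(track, [("chr1", 5_000, "-")], 2_000, 4)
        assert plus.matrix[0].tolist() == minus.matrix[0][::-1].tolist()

    def test_methylome_bins_without_cpgs_masked(self):
        track = track_from([4_900, 5_100], [0.2, 0.8])
        prof = metaprofile_anchor(track, [("chr1", 5_000, "+")], 2_000, 4)
        row = prof.matrix[0]
        assert np.isnan(row[[0, 3]]).all()
        assert row[1] == pytest.approx(0.2) and row[2] == pytest.approx(0.8)

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError):
            metaprofile_anchor(track_from([0], [0.5]), [], 2_000, 4)


class TestMetaprofileScaled:
    def gene(self, strand="+"):
        return GeneModel("g", "chr1", strand, 4_000, 6_000,
                         (GenomicInterval("chr1", 4_000, 6_000),))

    def test_body_vs_flank_indicator(self):
        # signal 1 inside the gene body, 0 outside
        values = np.zeros(10)
        values[4:6] = 1.0
        track = EnrichmentTrack(1000, SIZES, {"chr1": values})
        prof = metaprofile_scaled(track, [self.gene()], flank_bp=2_000,
                                  body_bins=4, flank_bins=2)
        row = prof.matrix[0]
        assert np.allclose(row[2:6], 1.0)
        assert np.allclose(row[:2], 0.0) and np.allclose(row[6:], 0.0)

    def test_strand_reversal_flips_row(self):
        values = np.arange(10, dtype=float)
        track = EnrichmentTrack(1000, SIZES, {"chr1": values})
        plus = metaprofile_scaled(track, [self.gene("+")], 2_000, 4, 2)
        minus = metaprofile_scaled(track, [self.gene("-")], 2_000, 4, 2)
        assert plus.matrix[0].tolist() == minus.matrix[0][::-1].tolist()

    def test_constant_methylome_flat(self):
        pos = np.arange(0, 10_000, 97)
        track = track_from(pos, np.full(len(pos), 0.7))
        prof = metaprofile_scaled(track, [self.gene()], 2_000, 4, 2)
        col = prof.column_means
        assert np.allclose(col[np.isfinite(col)], 0.7)


class TestExpressionGroups:
    def test_default_labels_and_assignment(self):
        g = ExpressionGroups()
        assert g.labels == ("<1", "1-250", ">250")
        assert g.assign(0.5) == "<1"
        assert g.assign(1.0) == "1-250"
        assert g.assign(250.0) == "1-250"
        assert g.assign(300.0) == ">250"

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            ExpressionGroups(edges=(250.0, 1.0))


class TestExpressionMethylationMatrix:
    def two_exon_gene(self):
        return GeneModel("g1", "chr1", "+", 2_000, 8_000,
                         (GenomicInterval("chr1", 2_000, 3_000),
                          GenomicInterval("chr1", 5_000, 8_000)))

    def test_identical_tracks_zero_matrix(self, rng):
        pos = np.arange(1_000, 9_000, 113)
        lev = rng.uniform(0, 1, len(pos))
        g = self.two_exon_gene()
        expr = pd.DataFrame({"gene_id": ["g1"], "fpkm": [10.0]})
        mat, missing = expression_methylation_matrix(
            [g], expr, track_from(pos, lev), track_from(pos, lev))
        assert missing == 0
        assert np.allclose(mat.to_numpy(float)[np.isfinite(mat.to_numpy(float))], 0.0)

    def test_promoter_delta_recovered(self):
        g = self.two_exon_gene()
        pos = np.array([1_500, 2_500, 6_000])     # promoter, exon1, exon2
        a = track_from(pos, [0.7, 0.5, 0.5])
        b = track_from(pos, [0.5, 0.5, 0.5])
        expr = pd.DataFrame({"gene_id": ["g1"], "fpkm": [0.2]})
        mat, _ = expression_methylation_matrix([g], expr, a, b)
        assert mat.loc["<1", "promoter"] == pytest.approx(0.2)
        assert mat.loc["<1", "exon_1"] == pytest.approx(0.0)

    def test_missing_expression_counted(self):
        g = self.two_exon_gene()
        pos = np.array([2_500])
        t = track_from(pos, [0.5])
        expr = pd.DataFrame({"gene_id": ["other"], "fpkm": [1.0]})
        mat, missing = expression_methylation_matrix([g], expr, t, t)
        assert missing == 1

    def test_matches_bruteforce_small_instance(self, rng):
        genes = [self.two_exon_gene()]
        pos = np.arange(1_200, 8_800, 53)
        a = track_from(pos, rng.uniform(0, 1, len(pos)))
        b = track_from(pos, rng.uniform(0, 1, len(pos)))
        expr = pd.DataFrame({"gene_id": ["g1"], "fpkm": [500.0]})
        mat, _ = expression_methylation_matrix(genes, expr, a, b)
        # brute force: promoter window is [tss-1000, tss+100]
        sel = (pos >= 1_000) & (pos <= 2_100)
        diff = a.df["level"].to_numpy() - b.df["level"].to_numpy()
        assert mat.loc[">250", "promoter"] == pytest.approx(diff[sel].mean())
        sel_intron = (pos >= 3_000) & (pos < 5_000)
        assert mat.loc[">250", "intron_1"] == pytest.approx(diff[sel_intron].mean())


class TestRegression:
    def test_exact_line(self):
        df = pd.DataFrame({"delta_meth": [-0.4, -0.2, 0.0, 0.2, 0.4]})
        df["delta_expr"] = -2.0 * df["delta_meth"]
        fit = delta_delta_regression(df)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.r == pytest.approx(-1.0)

    def test_constant_response_zero_slope(self):
        df = pd.DataFrame({"delta_meth": [-0.4, 0.0, 0.4],
                           "delta_expr": [1.0, 1.0, 1.0]})
        assert delta_delta_regression(df).slope == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"delta_meth": [0.1, 0.1, 0.1],
                           "delta_expr": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            delta_delta_regression(df)

    def test_recovers_known_slope_within_3se(self, rng):
        x = rng.uniform(-0.5, 0.5, 100)
        y = -3.0 * x + rng.normal(0, 0.5, 100)
        fit = delta_delta_regression(pd.DataFrame(
            {"delta_meth": x, "delta_expr": y}))
        se = 0.5 / (np.std(x) * np.sqrt(100))
        assert abs(fit.slope + 3.0) < 3 * se
        assert fit.p_value < 1e-10
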