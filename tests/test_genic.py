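"""Gene-body calls, feature annotation, regulatory domains, DMR set ops."""
import numpy as np
import pytest

from methwave.genic import (DomainParams, GenicParams, annotate_feature,
                            annotate_features, assign_dmrs_to_genes,
                            classify_gene_bodies, gene_body_fraction,
                            intersect_dmr_sets, overlap_with_peaks,
                            regulatory_domains)
from methwave.types import Dmr, GeneModel, GenomicInterval, make_dmr


def gene(gene_id="g", chrom="chr1", strand="+", start=0, end=10_000,
         exons=None, **kw):
    if exons is None:
        exons = (GenomicInterval(chrom, start, end),)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=start, end=end, exons=tuple(exons), **kw)


def span_dmr(chrom, start, end, sign=-1, name=""):
    """DMR whose member CpGs span exactly [start, end)."""
    pos = [start, (start + end) // 2, end - 2]
    return make_dmr(chrom, pos, sign * 0.5, name=name)


class TestGeneBodyFraction:
    def test_fraction_and_direction(self):
        g = gene(end=10_000)
        call = gene_body_fraction(g, [span_dmr("chr1", 2000, 5000)])
        assert call.covered_fraction == pytest.approx(0.30)
        assert call.direction == "hypo"

    def test_exact_quarter_does_not_qualify(self):
        g = gene(end=10_000)
        dmrs = [span_dmr("chr1", 2000, 4500)]
        call = gene_body_fraction(g, dmrs)
        assert call.covered_fraction == pytest.approx(0.25)
        result = classify_gene_bodies([g], dmrs, mode="es_vs_adult")
        assert len(result.table) == 0

    def test_short_gene_excluded(self):
        g = gene(end=400)
        with pytest.raises(ValueError, match="shorter"):
            gene_body_fraction(g, [])
        result = classify_gene_bodies([g], [], mode="es_vs_adult")
        assert result.excluded_short == ("g",)

    def test_short_dmrs_ignored_in_es_mode(self):
        g = gene(end=10_000)
        short = make_dmr("chr1", [3000, 3400, 3798], -0.5)  # 800 bp
        call = gene_body_fraction(g, [short], GenicParams.for_mode("es_vs_adult"))
        assert call.covered_fraction == 0.0
        call2 = gene_body_fraction(g, [short], GenicParams.for_mode("postnatal"))
        assert call2.covered_fraction == pytest.approx(0.08)

    def test_mixed_direction(self):
        g = gene(end=10_000)
        dmrs = [span_dmr("chr1", 1000, 3000, sign=-1),
                span_dmr("chr1", 6000, 8000, sign=+1)]
        call = gene_body_fraction(g, dmrs)
        assert call.direction == "mixed"
        assert call.covered_fraction == pytest.approx(0.4)

    def test_overlapping_dmrs_counted_once(self):
        g = gene(end=10_000)
        dmrs = [span_dmr("chr1", 2000, 5000), span_dmr("chr1", 4000, 6000)]
        call = gene_body_fraction(g, dmrs)
        assert call.covered_fraction == pytest.approx(0.4)


class TestClassifyGeneBodies:
    def setup_method(self):
        self.genes = [gene("gA", start=0, end=10_000),
                      gene("gB", start=20_000, end=30_000),
                      gene("gC", start=40_000, end=50_000)]
        self.dmrs = [span_dmr("chr1", 2000, 5000),        # 30% of gA
                     span_dmr("chr1", 21_000, 22_000)]     # 10% of gB

    def test_es_vs_adult_mode(self):
        result = classify_gene_bodies(self.genes, self.dmrs, "es_vs_adult")
        assert result.table["gene_id"].tolist() == ["gA"]
        assert result.hypo_ids == ["gA"]

    def test_postnatal_mode(self):
        result = classify_gene_bodies(self.genes, self.dmrs, "postnatal")
        assert sorted(result.table["gene_id"]) == ["gA", "gB"]

    def test_no_dmrs_empty(self):
        result = classify_gene_bodies(self.genes, [], "es_vs_adult")
        assert len(result.table) == 0 and len(result.mixed) == 0


class TestFeatureAnnotation:
    def setup_method(self):
        exons = (GenomicInterval("chr1", 10_000, 10_500),
                 GenomicInterval("chr1", 12_000, 12_500),
                 GenomicInterval("chr1", 14_000, 15_000))
        self.gene = gene("g", start=10_000, end=15_000, exons=exons)

    def annotate_mid(self, mid, genes=None):
        d = make_dmr("chr1", [mid - 50, mid + 48], -0.5)
        return annotate_feature(d, genes or [self.gene]).category

    def test_promoter_upstream_of_tss(self):
        assert self.annotate_mid(10_000 - 50) == "promoter"

    def test_tts_window_downstream_of_tes(self):
        assert self.annotate_mid(15_000 - 1 + 600) == "TTS"

    def test_exon_and_intron(self):
        assert self.annotate_mid(12_250) == "exon"
        assert self.annotate_mid(13_000) == "intron"

    def test_intergenic(self):
        assert self.annotate_mid(50_000) == "intergenic"

    def test_minus_strand_promoter_flips(self):
        g = gene("m", strand="-", start=10_000, end=15_000)
        d = make_dmr("chr1", [15_000 + 400, 15_000 + 500], -0.5)
        assert annotate_feature(d, [g]).category == "promoter"

    def test_utrs_with_cds(self):
        g = gene("c", start=10_000, end=15_000,
                 exons=(GenomicInterval("chr1", 10_000, 11_000),
                        GenomicInterval("chr1", 14_000, 15_000)),
                 cds_start=10_500, cds_end=14_500)
        d5 = make_dmr("chr1", [10_200, 10_300], -0.5)
        d3 = make_dmr("chr1", [14_600, 14_700], -0.5)
        assert annotate_feature(d5, [g]).category == "5'UTR"
        # 3'UTR midpoint lands in the TTS window here; place it clear of TES
        g2 = gene("c2", start=10_000, end=20_000,
                  exons=(GenomicInterval("chr1", 10_000, 11_000),
                         GenomicInterval("chr1", 14_000, 18_000)),
                  cds_start=10_500, cds_end=14_500)
        d3b = make_dmr("chr1", [15_500, 15_600], -0.5)
        assert annotate_feature(d3b, [g2]).category == "3'UTR"

    def test_island_and_shore_context(self):
        cgi = [GenomicInterval("chr1", 12_000, 12_400)]
        on = make_dmr("chr1", [12_100, 12_200], -0.5)
        near = make_dmr("chr1", [13_000, 13_100], -0.5)
        far = make_dmr("chr1", [20_000, 20_100], -0.5)
        assert annotate_feature(on, [], cgi).island_context == "CpG-island"
        assert annotate_feature(near, [], cgi).island_context == "CpG-shore"
        assert annotate_feature(far, [], cgi).island_context is None

    def test_every_dmr_gets_exactly_one_category(self, rng):
        dmrs = [make_dmr("chr1", [int(p), int(p) + 100], -0.5, name=f"d{i}")
                for i, p in enumerate(rng.integers(0, 60_000, 40))]
        table = annotate_features(dmrs, [self.gene])
        assert len(table) == 40
        assert table["category"].notna().all()


class TestRegulatoryDomains:
    def test_lone_gene_full_extension(self):
        g = gene("g", start=100_000, end=120_000)
        dom = regulatory_domains([g])["g"]
        assert (dom.start, dom.end) == (45_000, 151_000)

    def test_neighbour_clips_extension(self):
        g1 = gene("g1", start=100_000, end=104_000)
        g2 = gene("g2", start=110_000, end=114_000)
        doms = regulatory_domains([g1, g2])
        assert doms["g1"].end == 105_000        # g2 basal starts there
        assert doms["g2"].start == 101_000      # g1 basal ends there

    def test_chromosome_start_clip(self):
        g = gene("g", start=2_000, end=8_000)
        dom = regulatory_domains([g])["g"]
        assert dom.start == 0

    def test_domain_contains_basal_even_when_overlapping(self):
        g1 = gene("g1", start=100_000, end=104_000)
        g2 = gene("g2", start=100_500, end=104_500)   # basals overlap
        doms = regulatory_domains([g1, g2])
        assert doms["g1"].start <= 95_000 and doms["g1"].end >= 101_000
        assert doms["g2"].start <= 95_500 and doms["g2"].end >= 101_500

    def test_order_independence(self, rng):
        for _ in range(100):
            starts = np.sort(rng.choice(np.arange(10_000, 2_000_000, 100),
                                        size=8, replace=False))
            genes = [gene(f"g{i}", start=int(s), end=int(s) + 2_000,
                          strand="+" if rng.random() < 0.5 else "-")
                     for i, s in enumerate(starts)]
            fwd = regulatory_domains(genes)
            rev = regulatory_domains(genes[::-1])
            assert fwd == rev

    def test_extension_capped_at_50kb(self, rng):
        g = gene("g", start=500_000, end=520_000)
        dom = regulatory_domains([g])["g"]
        params = DomainParams()
        assert dom.start >= 500_000 - params.basal_up_bp - params.extension_bp
        assert dom.end <= 500_000 + params.basal_down_bp + params.extension_bp


class TestAssignment:
    def test_great_style_assignment(self):
        g1 = gene("g1", start=100_000, end=104_000)
        g2 = gene("g2", start=110_000, end=114_000)
        doms = regulatory_domains([g1, g2])
        inside = span_dmr("chr1", 98_000, 99_000, name="in1")
        shared = span_dmr("chr1", 104_800, 105_600, name="both")
        outside = span_dmr("chr1", 500_000, 501_000, name="out")
        table = assign_dmrs_to_genes([inside, shared, outside], doms)
        by_dmr = table.groupby("dmr_id")["gene_id"].agg(set).to_dict()
        assert by_dmr["in1"] == {"g1"}
        assert by_dmr["both"] == {"g1", "g2"}
        assert "out" not in by_dmr


class TestDmrSetOps:
    def test_disjoint_sets(self):
        a = [span_dmr("chr1", 0, 1000)]
        b = [span_dmr("chr1", 5000, 6000)]
        res = intersect_dmr_sets(a, b)
        assert res.counts == {"a_only": 1, "a_common": 0,
                              "b_common": 0, "b_only": 1}

    def test_identical_sets_all_common(self):
        a = [span_dmr("chr1", 0, 1000), span_dmr("chr1", 5000, 6000)]
        res = intersect_dmr_sets(a, list(a))
        assert res.counts["a_common"] == 2 and res.counts["b_common"] == 2

    def test_matches_allpairs_bruteforce(self, rng):
        def random_set(n):
            out = []
            for i in range(n):
                s = int(rng.integers(0, 50_000))
                out.append(span_dmr("chr1", s, s + int(rng.integers(200, 2000)),
                                    name=f"r{i}"))
            return out
        a, b = random_set(30), random_set(30)
        res = intersect_dmr_sets(a, b)
        brute_a = sum(
            any(min(x.end, y.end) - max(x.start, y.start) >= 1 for y in b)
            for x in a)
        assert res.counts["a_common"] == brute_a
        # symmetry of the common relation at 1 bp
        res_swapped = intersect_dmr_sets(b, a)
        assert res.counts["a_common"] == res_swapped.counts["b_common"]

    def test_peak_overlap_fraction(self):
        dmrs = [span_dmr("chr1", i * 10_000, i * 10_000 + 1000, name=f"d{i}")
                for i in range(10)]
        peaks = [GenomicInterval("chr1", i * 10_000 + 500, i * 10_000 + 700)
                 for i in range(3)]
        frac, flags = overlap_with_peaks(dmrs, peaks)
        assert frac == pytest.approx(0.30)
        assert overlap_with_peaks(dmrs, [])[0] == 0.0
        tiling = [GenomicInterval("chr1", 0, 1_000_000)]
        assert overlap_with_peaks(dmrs, tiling)[0] == 1.0
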