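"""Gene-body methylation classification, feature and regulatory-domain
annotation of DMRs, and DMR set comparisons.

Gene-body calls measure what fraction of a gene's genomic span (TSS to TES)
is covered by qualifying DMRs.  Two modes mirror the two developmental
comparisons: the embryonic-versus-adult mode requires DMRs of at least 1 kb
covering strictly more than 25% of the body; the postnatal mode accepts any
DMR and a strictly-greater-than-5% cutoff.  Genes shorter than 500 bp are
excluded from every analysis.

Regulatory domains follow the GREAT basal-plus-extension rule: a basal
domain from 5 kb upstream to 1 kb downstream of the TSS, extended on both
sides by up to 50 kb but stopping at the nearest other gene's basal domain.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import Interval, IntervalTree

from .types import Dmr, GeneModel, GenomicInterval, PairedTrack


@dataclass(frozen=True)
class GenicParams:
    """Cutoffs for differential gene-body methylation.

    body_fraction_min: strict lower bound on the covered fraction
        (0.25 in es_vs_adult mode, 0.05 in postnatal mode).
    min_dmr_len_bp: minimal DMR length counted toward coverage (1,000 bp in
        es_vs_adult mode; no floor in postnatal mode).
    min_gene_len_bp: genes shorter than this are excluded (500 bp).
    """

    body_fraction_min: float = 0.25
    min_dmr_len_bp: int = 1000
    min_gene_len_bp: int = 500

    def __post_init__(self) -> None:
        if self.body_fraction_min <= 0 or self.min_gene_len_bp <= 0:
            raise ValueError("parameters must be positive")
        if self.min_dmr_len_bp < 0:
            raise ValueError("min_dmr_len_bp must be >= 0")

    @classmethod
    def for_mode(cls, mode: str) -> "GenicParams":
        if mode == "es_vs_adult":
            return cls(body_fraction_min=0.25, min_dmr_len_bp=1000)
        if mode == "postnatal":
            return cls(body_fraction_min=0.05, min_dmr_len_bp=0)
        raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class GeneBodyCall:
    gene_id: str
    covered_fraction: float
    direction: str               # hyper | hypo | mixed | none
    mean_level_a: Optional[float] = None
    mean_level_b: Optional[float] = None


@dataclass(frozen=True)
class DomainParams:
    """GREAT-style basal-plus-extension regulatory domain geometry (bp)."""

    basal_up_bp: int = 5000
    basal_down_bp: int = 1000
    extension_bp: int = 50000

    def __post_init__(self) -> None:
        if min(self.basal_up_bp, self.basal_down_bp, self.extension_bp) <= 0:
            raise ValueError("domain parameters must be positive")


@dataclass(frozen=True)
class FeatureAnnotation:
    dmr_id: str
    category: str                # promoter|TTS|5'UTR|3'UTR|exon|intron|intergenic
    island_context: Optional[str] = None   # CpG-island | CpG-shore | None


def _union_bp(spans: list[tuple[int, int]]) -> int:
    if not spans:
        return 0
    spans.sort()
    total, cur_s, cur_e = 0, *spans[0]
    for s, e in spans[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def gene_body_fraction(gene: GeneModel, dmrs: Sequence[Dmr],
                       params: GenicParams = GenicParams(),
                       paired: Optional[PairedTrack] = None) -> GeneBodyCall:
    """Fraction of the gene span covered by qualifying DMRs.

    Coverage counts DMRs at least ``min_dmr_len_bp`` long, clipped to the
    gene span and unioned per direction.  Direction is "mixed" when both
    hypo and hyper DMRs cover >0 bp, else the sign of the covering DMRs
    ("none" if nothing overlaps).  If a paired track is given, mean raw
    levels over gene-body CpGs are reported per sample.
    """
    if gene.length < params.min_gene_len_bp:
        raise ValueError(
            f"gene {gene.gene_id} shorter than {params.min_gene_len_bp} bp; "
            "exclude it upstream"
        )
    spans: dict[str, list[tuple[int, int]]] = {"hyper": [], "hypo": []}
    for d in dmrs:
        if d.chrom != gene.chrom or d.length < params.min_dmr_len_bp:
            continue
        s, e = max(d.start, gene.start), min(d.end, gene.end)
        if s < e:
            spans[d.direction].append((s, e))
    bp = {k: _union_bp(list(v)) for k, v in spans.items()}
    covered = _union_bp(spans["hyper"] + spans["hypo"])
    if bp["hyper"] > 0 and bp["hypo"] > 0:
        direction = "mixed"
    elif bp["hyper"] > 0:
        direction = "hyper"
    elif bp["hypo"] > 0:
        direction = "hypo"
    else:
        direction = "none"
    mean_a = mean_b = None
    if paired is not None and len(paired):
        sel = ((paired.df["chrom"] == gene.chrom)
               & (paired.df["pos"] >= gene.start)
               & (paired.df["pos"] < gene.end))
        if sel.any():
            mean_a = float(paired.df.loc[sel, "level_a"].mean())
            mean_b = float(paired.df.loc[sel, "level_b"].mean())
    return GeneBodyCall(gene_id=gene.gene_id,
                        covered_fraction=covered / gene.length,
                        direction=direction,
                        mean_level_a=mean_a, mean_level_b=mean_b)


@dataclass(frozen=True)
class GeneBodyClassification:
    """Qualifying genes split by direction; mixed-direction and short genes
    reported separately."""

    table: pd.DataFrame          # gene_id, covered_fraction, direction
    mixed: pd.DataFrame
    excluded_short: tuple[str, ...]

    @property
    def hyper_ids(self) -> list[str]:
        return list(self.table.loc[self.table["direction"] == "hyper", "gene_id"])

    @property
    def hypo_ids(self) -> list[str]:
        return list(self.table.loc[self.table["direction"] == "hypo", "gene_id"])


def classify_gene_bodies(genes: Sequence[GeneModel], dmrs: Sequence[Dmr],
                         mode: str = "es_vs_adult",
                         paired: Optional[PairedTrack] = None,
                         ) -> GeneBodyClassification:
    """Genes whose bodies are covered strictly more than the mode cutoff.

    es_vs_adult: fraction > 0.25, DMRs >= 1 kb only.
    postnatal:   fraction > 0.05, any DMR length.
    """
    params = GenicParams.for_mode(mode)
    rows, mixed_rows, excluded = [], [], []
    for g in genes:
        if g.length < params.min_gene_len_bp:
            excluded.append(g.gene_id)
            continue
        call = gene_body_fraction(g, dmrs, params, paired=paired)
        if call.covered_fraction > params.body_fraction_min:
            row = {"gene_id": g.gene_id,
                   "covered_fraction": call.covered_fraction,
                   "direction": call.direction}
            (mixed_rows if call.direction == "mixed" else rows).append(row)
    cols = ["gene_id", "covered_fraction", "direction"]
    return GeneBodyClassification(
        table=pd.DataFrame(rows, columns=cols),
        mixed=pd.DataFrame(mixed_rows, columns=cols),
        excluded_short=tuple(excluded),
    )


# Homer-style promoter window and the terminator (TTS) window, in
# transcription-direction offsets relative to TSS / TES.
PROMOTER_UP_BP = 1000
PROMOTER_DOWN_BP = 100
TTS_UP_BP = 100
TTS_DOWN_BP = 1000
SHORE_BP = 2000

FEATURE_PRECEDENCE = ("promoter", "TTS", "5'UTR", "3'UTR", "exon", "intron")


def _tx_offset(pos: int, anchor: int, strand: str) -> int:
    """Signed offset of pos from anchor in transcription direction
    (negative = upstream)."""
    return pos - anchor if strand == "+" else anchor - pos


def _gene_feature(mid: int, gene: GeneModel) -> Optional[str]:
    """Feature category of a point with respect to one gene, or None."""
    off_tss = _tx_offset(mid, gene.tss, gene.strand)
    if -PROMOTER_UP_BP <= off_tss <= PROMOTER_DOWN_BP:
        return "promoter"
    off_tes = _tx_offset(mid, gene.tes, gene.strand)
    if -TTS_UP_BP <= off_tes <= TTS_DOWN_BP:
        return "TTS"
    if not (gene.start <= mid < gene.end):
        return None
    in_exon = any(e.start <= mid < e.end for e in gene.exons)
    if in_exon and gene.cds_start is not None:
        # UTR = exonic sequence outside the coding region, split by side
        if mid < gene.cds_start:
            return "5'UTR" if gene.strand == "+" else "3'UTR"
        if mid >= gene.cds_end:
            return "3'UTR" if gene.strand == "+" else "5'UTR"
    return "exon" if in_exon else "intron"


def annotate_feature(dmr: Dmr, genes: Sequence[GeneModel],
                     cpg_islands: Sequence[GenomicInterval] = (),
                     ) -> FeatureAnnotation:
    """Assign the DMR midpoint to exactly one gene-feature category.

    Precedence over all genes: promoter > TTS > 5'UTR > 3'UTR > exon >
    intron > intergenic.  CpG-island overlap (of the DMR span) or shore
    (within 2 kb of an island) is reported as a second, independent label.
    """
    mid = (dmr.start + dmr.end) // 2
    hits = {
        f for g in genes if g.chrom == dmr.chrom
        for f in [_gene_feature(mid, g)] if f is not None
    }
    category = next((f for f in FEATURE_PRECEDENCE if f in hits), "intergenic")
    island = None
    for iv in cpg_islands:
        if iv.chrom != dmr.chrom:
            continue
        if dmr.start < iv.end and iv.start < dmr.end:
            island = "CpG-island"
            break
        if dmr.start < iv.end + SHORE_BP and iv.start - SHORE_BP < dmr.end:
            island = "CpG-shore"
    return FeatureAnnotation(dmr_id=dmr.dmr_id, category=category,
                             island_context=island)


def annotate_features(dmrs: Sequence[Dmr], genes: Sequence[GeneModel],
                      cpg_islands: Sequence[GenomicInterval] = (),
                      ) -> pd.DataFrame:
    recs = [annotate_feature(d, genes, cpg_islands) for d in dmrs]
    return pd.DataFrame({
        "dmr_id": [r.dmr_id for r in recs],
        "category": [r.category for r in recs],
        "island_context": [r.island_context for r in recs],
    })


def basal_domain(gene: GeneModel, params: DomainParams = DomainParams()
                 ) -> tuple[int, int]:
    """Strand-adjusted basal regulatory window around the TSS (may be
    clipped at position 0)."""
    if gene.strand == "+":
        s, e = gene.tss - params.basal_up_bp, gene.tss + params.basal_down_bp
    else:
        s, e = gene.tss + 1 - params.basal_down_bp, gene.tss + 1 + params.basal_up_bp
    return max(0, s), e


def regulatory_domains(genes: Sequence[GeneModel],
                       params: DomainParams = DomainParams(),
                       chrom_sizes: Optional[dict[str, int]] = None,
                       ) -> dict[str, GenomicInterval]:
    """Basal-plus-extension regulatory domain per gene.

    Each basal window extends on both sides by up to ``extension_bp`` but
    stops at the nearest other gene's basal window (and at chromosome
    bounds); a domain never shrinks below its own basal window even when
    basal windows overlap.  The result is independent of gene order.
    """
    basal = {g.gene_id: basal_domain(g, params) for g in genes}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        s, e = basal[g.gene_id]
        by_chrom.setdefault(g.chrom, []).append((s, e, g.gene_id))
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        bs, be = basal[g.gene_id]
        others = [(s, e) for s, e, gid in by_chrom[g.chrom] if gid != g.gene_id]
        left_limit = max((e for s, e in others if e <= bs), default=0)
        right_cap = chrom_sizes.get(g.chrom) if chrom_sizes else None
        right_limit = min((s for s, e in others if s >= be),
                          default=right_cap if right_cap is not None else None)
        left = max(bs - params.extension_bp, left_limit, 0)
        right = be + params.extension_bp
        if right_limit is not None:
            right = min(right, right_limit)
        if right_cap is not None:
            right = min(right, right_cap)
        # overlapping basal windows: never shrink below own basal
        left = min(left, bs)
        right = max(right, be)
        out[g.gene_id] = GenomicInterval(g.chrom, left, right,
                                         strand=g.strand, name=g.gene_id)
    return out


def assign_dmrs_to_genes(dmrs: Sequence[Dmr],
                         domains: dict[str, GenomicInterval]) -> pd.DataFrame:
    """GREAT-style assignment: a DMR maps to every gene whose regulatory
    domain it overlaps by at least 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for gid, iv in domains.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gid)
    rows = []
    for d in dmrs:
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(d.start, d.end), key=lambda h: h.data):
            rows.append({"dmr_id": d.dmr_id, "gene_id": hit.data})
    return pd.DataFrame(rows, columns=["dmr_id", "gene_id"])


@dataclass(frozen=True)
class DmrSetIntersection:
    """Venn-style comparison of two DMR sets, counted from each side."""

    a_only: tuple[Dmr, ...]
    a_common: tuple[Dmr, ...]
    b_common: tuple[Dmr, ...]
    b_only: tuple[Dmr, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {"a_only": len(self.a_only), "a_common": len(self.a_common),
                "b_common": len(self.b_common), "b_only": len(self.b_only)}


def intersect_dmr_sets(set_a: Sequence[Dmr], set_b: Sequence[Dmr],
                       min_overlap_bp: int = 1) -> DmrSetIntersection:
    """A DMR is "common" iff it overlaps any DMR of the other set by at
    least ``min_overlap_bp``; counts are reported from both sides since the
    relation need not be one-to-one."""

    def split(xs, ys):
        trees: dict[str, IntervalTree] = {}
        for y in ys:
            trees.setdefault(y.chrom, IntervalTree()).addi(y.start, y.end)
        common, only = [], []
        for x in xs:
            tree = trees.get(x.chrom)
            best = 0
            if tree is not None:
                for hit in tree.overlap(x.start, x.end):
                    best = max(best, min(hit.end, x.end) - max(hit.begin, x.start))
            (common if best >= min_overlap_bp else only).append(x)
        return tuple(common), tuple(only)

    a_common, a_only = split(set_a, set_b)
    b_common, b_only = split(set_b, set_a)
    return DmrSetIntersection(a_only=a_only, a_common=a_common,
                              b_common=b_common, b_only=b_only)


def overlap_with_peaks(dmrs: Sequence[Dmr],
                       peaks: Sequence[GenomicInterval],
                       ) -> tuple[float, list[bool]]:
    """Fraction of DMRs overlapping at least one peak (>= 1 bp)."""
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    flags = [
        d.chrom in trees and bool(trees[d.chrom].overlap(d.start, d.end))
        for d in dmrs
    ]
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags
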