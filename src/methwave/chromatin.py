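"""Binned ChIP enrichment, metaprofiles and methylation-expression matrices.

ChIP and input read piles are binned genome-wide, normalized to reads per
kilobase per million mapped reads (RPKM), and compared as
log2((ChIP + c) / (input + c)) with a small pseudocount c that defines the
ratio at empty bins.  Metaprofiles average a signal track over anchored
windows (e.g. TSSs) or over gene bodies rescaled to percent coordinates,
orientation-flipping minus-strand regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genic import PROMOTER_DOWN_BP, PROMOTER_UP_BP
from .types import GeneModel, GenomicInterval, MethylomeTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichParams:
    """bin_bp: genome bin width (bp); pseudocount_rpkm: added to both RPKM
    values so the log ratio is defined at empty bins."""

    bin_bp: int = 1000
    pseudocount_rpkm: float = 0.25

    def __post_init__(self) -> None:
        if self.bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        if self.pseudocount_rpkm <= 0:
            raise ValueError("pseudocount_rpkm must be positive")


class EnrichmentTrack:
    """Fixed-width genome bins carrying RPKM or log2-ratio values."""

    def __init__(self, bin_bp: int, chrom_sizes: dict[str, int],
                 values: dict[str, np.ndarray]):
        self.bin_bp = int(bin_bp)
        self.chrom_sizes = dict(chrom_sizes)
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // self.bin_bp)
            if chrom not in self.values or len(self.values[chrom]) != n:
                raise ValueError(f"bins do not tile chromosome {chrom}")
            if np.isnan(self.values[chrom]).any():
                raise ValueError(f"NaN bin value on {chrom}")

    def compatible(self, other: "EnrichmentTrack") -> bool:
        return (self.bin_bp == other.bin_bp
                and self.chrom_sizes == other.chrom_sizes)

    def value_at(self, chrom: str, pos: int) -> float:
        """Value of the bin containing pos; NaN outside the genome."""
        vals = self.values.get(chrom)
        if vals is None or not 0 <= pos < self.chrom_sizes[chrom]:
            return float("nan")
        return float(vals[pos // self.bin_bp])


def _five_prime(read: GenomicInterval) -> int:
    return read.end - 1 if read.strand == "-" else read.start


def bin_rpkm(reads: Sequence[GenomicInterval], chrom_sizes: dict[str, int],
             params: EnrichParams = EnrichParams(),
             total_reads: Optional[int] = None) -> EnrichmentTrack:
    """Count read 5' ends per fixed-width bin and normalize to RPKM.

    RPKM(bin) = count / ((bin_kb) * (total_reads / 1e6)); the trailing
    partial bin of each chromosome is normalized by its actual width.
    ``total_reads`` defaults to the number of reads supplied (override it
    with the library's mapped-read total when binning a subset).
    """
    if total_reads is None:
        total_reads = len(reads)
    if total_reads < 1:
        raise ValueError("total read count must be >= 1")
    bb = params.bin_bp
    counts = {c: np.zeros(-(-size // bb), dtype=np.int64)
              for c, size in chrom_sizes.items()}
    for r in reads:
        if r.chrom not in counts:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        p = _five_prime(r)
        if not 0 <= p < chrom_sizes[r.chrom]:
            raise ValueError(f"read 5' end {p} outside chromosome {r.chrom}")
        counts[r.chrom][p // bb] += 1
    per_million = total_reads / 1e6
    values = {}
    for chrom, cnt in counts.items():
        width = np.full(len(cnt), bb, dtype=float)
        width[-1] = chrom_sizes[chrom] - (len(cnt) - 1) * bb
        values[chrom] = cnt / ((width / 1000.0) * per_million)
    return EnrichmentTrack(bb, chrom_sizes, values)


def log2_enrichment(chip: EnrichmentTrack, input_: EnrichmentTrack,
                    params: EnrichParams = EnrichParams()) -> EnrichmentTrack:
    """Per-bin log2((ChIP RPKM + c) / (input RPKM + c))."""
    if not chip.compatible(input_):
        raise ValueError("ChIP and input tracks have mismatched bins")
    c = params.pseudocount_rpkm
    values = {
        chrom: np.log2((chip.values[chrom] + c) / (input_.values[chrom] + c))
        for chrom in chip.chrom_sizes
    }
    return EnrichmentTrack(chip.bin_bp, chip.chrom_sizes, values)


@dataclass
class MetaProfile:
    """Per-region signal matrix plus masked column means.

    matrix: regions x bins, NaN where a bin had no data (no CpGs, or
    outside the genome).  Minus-strand regions are already flipped so
    columns read 5' to 3'.
    """

    matrix: np.ndarray
    bin_labels: tuple[str, ...]

    @property
    def column_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)


Track = Union[EnrichmentTrack, MethylomeTrack]


def _sample_bins(track: Track, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Mean signal per [edges[k], edges[k+1]) bin; NaN for empty/out-of-
    range bins.  Enrichment tracks are sampled at bin centers; methylome
    tracks average the raw per-CpG levels falling in the bin."""
    out = np.full(len(edges) - 1, np.nan)
    if isinstance(track, EnrichmentTrack):
        centers = (edges[:-1] + edges[1:]) // 2
        for k, c in enumerate(centers):
            out[k] = track.value_at(chrom, int(c))
        return out
    sub = track.df[track.df["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    lev = sub["level"].to_numpy()
    idx = np.searchsorted(pos, edges)
    for k in range(len(edges) - 1):
        lo, hi = idx[k], idx[k + 1]
        if hi > lo:
            out[k] = lev[lo:hi].mean()
    return out


def metaprofile_anchor(track: Track,
                       anchors: Sequence[tuple[str, int, str]],
                       flank_bp: int = 5000, n_bins: int = 50) -> MetaProfile:
    """Signal around stranded anchor points, e.g. TF binding sites or TSSs.

    Each row samples ``n_bins`` equal-bp bins over [anchor - flank_bp,
    anchor + flank_bp); minus-strand rows are reversed so upstream is
    always left.  Column means ignore NaN (masked) bins.
    """
    if not anchors:
        raise ValueError("no anchors supplied")
    if 2 * flank_bp % n_bins:
        raise ValueError("2*flank_bp must be divisible by n_bins")
    rows = []
    for chrom, pos, strand in anchors:
        edges = pos - flank_bp + np.arange(n_bins + 1) * (2 * flank_bp // n_bins)
        row = _sample_bins(track, chrom, edges)
        # bins extending past the chromosome start are masked
        row[edges[1:] <= 0] = np.nan
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    labels = tuple(
        f"{(-flank_bp + k * 2 * flank_bp // n_bins)}bp" for k in range(n_bins)
    )
    return MetaProfile(matrix=np.vstack(rows), bin_labels=labels)


def metaprofile_scaled(track: Track, genes: Sequence[GeneModel],
                       flank_bp: int = 5000, body_bins: int = 40,
                       flank_bins: int = 10) -> MetaProfile:
    """Gene-scaled metaprofile: fixed-bp flanks around TSS and TES with the
    gene body rescaled to ``body_bins`` percent-of-gene bins; minus-strand
    genes are orientation-flipped."""
    if flank_bp % flank_bins:
        raise ValueError("flank_bp must be divisible by flank_bins")
    rows = []
    for g in genes:
        up = g.start - flank_bp + np.arange(flank_bins + 1) * (flank_bp // flank_bins)
        body = np.unique(np.linspace(g.start, g.end, body_bins + 1).astype(np.int64))
        if len(body) < body_bins + 1:
            # genes shorter than body_bins bp: sample what exists
            body = np.linspace(g.start, g.end, body_bins + 1)
            body = np.floor(body).astype(np.int64)
            body[-1] = g.end
        down = g.end + np.arange(flank_bins + 1) * (flank_bp // flank_bins)
        row = np.concatenate([
            _sample_bins(track, g.chrom, up),
            _sample_bins_edges_safe(track, g.chrom, body),
            _sample_bins(track, g.chrom, down),
        ])
        row[:flank_bins][up[1:] <= 0] = np.nan
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
    labels = (tuple(f"up{k}" for k in range(flank_bins))
              + tuple(f"body{k}" for k in range(body_bins))
              + tuple(f"down{k}" for k in range(flank_bins)))
    return MetaProfile(matrix=np.vstack(rows), bin_labels=labels)


def _sample_bins_edges_safe(track: Track, chrom: str,
                            edges: np.ndarray) -> np.ndarray:
    """Like _sample_bins but tolerant of repeated edges (tiny genes):
    zero-width bins are NaN-masked."""
    out = _sample_bins(track, chrom, np.maximum.accumulate(edges))
    out[np.diff(np.maximum.accumulate(edges)) == 0] = np.nan
    return out


@dataclass(frozen=True)
class ExpressionGroups:
    """FPKM thresholds partitioning genes into expression groups.

    Default edges (1, 250) reproduce the "very low" (<1 FPKM) and "high"
    (>250 FPKM) groups with one intermediate stratum.
    """

    edges: tuple[float, ...] = (1.0, 250.0)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("group edges must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.edges
        inner = tuple(f"{a:g}-{b:g}" for a, b in zip(e, e[1:]))
        return (f"<{e[0]:g}",) + inner + (f">{e[-1]:g}",)

    def assign(self, fpkm: float) -> str:
        k = int(np.searchsorted(self.edges, fpkm, side="right"))
        if fpkm == self.edges[-1]:          # ">250" is strict
            k = len(self.edges) - 1
        return self.labels[k]


def _gene_features(gene: GeneModel, max_ordinal: int = 3
                   ) -> list[tuple[str, int, int]]:
    """(label, start, end) sub-regions of a gene in transcription order:
    promoter, then exon_1, intron_1, ...; ordinals past ``max_ordinal`` are
    pooled into exon_rest / intron_rest."""
    if gene.strand == "+":
        prom = (gene.tss - PROMOTER_UP_BP, gene.tss + PROMOTER_DOWN_BP + 1)
    else:
        prom = (gene.tss - PROMOTER_DOWN_BP, gene.tss + PROMOTER_UP_BP + 1)
    feats = [("promoter", max(0, prom[0]), prom[1])]

    def add(kind, k, iv):
        label = f"{kind}_{k}" if k <= max_ordinal else f"{kind}_rest"
        feats.append((label, iv.start, iv.end))

    for k, ex in enumerate(gene.exons_5to3(), start=1):
        add("exon", k, ex)
    for k, intr in enumerate(gene.introns_5to3(), start=1):
        add("intron", k, intr)
    return feats


def expression_methylation_matrix(genes: Sequence[GeneModel],
                                  expression: pd.DataFrame,
                                  meth_a: MethylomeTrack,
                                  meth_b: MethylomeTrack,
                                  groups: ExpressionGroups = ExpressionGroups(),
                                  max_ordinal: int = 3,
                                  ) -> tuple[pd.DataFrame, int]:
    """Mean methylation difference (A - B) per expression group and gene
    feature.

    ``expression`` needs columns gene_id and fpkm.  Per gene and feature the
    difference is averaged over the feature's CpGs, then averaged over the
    genes of each expression group (features with no CpGs are ignored).
    Returns (matrix, n_genes_missing_expression).
    """
    fpkm = dict(zip(expression["gene_id"], expression["fpkm"]))
    merged = meth_a.df.merge(meth_b.df, on=["chrom", "pos"],
                             suffixes=("_a", "_b"))
    cells: dict[tuple[str, str], list[float]] = {}
    n_missing = 0
    for g in genes:
        if g.gene_id not in fpkm:
            n_missing += 1
            continue
        group = groups.assign(float(fpkm[g.gene_id]))
        sub = merged[merged["chrom"] == g.chrom]
        pos = sub["pos"].to_numpy()
        dif = (sub["level_a"] - sub["level_b"]).to_numpy()
        for label, s, e in _gene_features(g, max_ordinal):
            lo, hi = np.searchsorted(pos, [s, e])
            if hi > lo:
                cells.setdefault((group, label), []).append(
                    float(dif[lo:hi].mean()))
    feature_order = ["promoter"]
    for k in range(1, max_ordinal + 1):
        feature_order += [f"exon_{k}", f"intron_{k}"]
    feature_order += ["exon_rest", "intron_rest"]
    used = {lab for (_, lab) in cells}
    feature_order = [f for f in feature_order if f in used]
    mat = pd.DataFrame(index=list(groups.labels), columns=feature_order,
                       dtype=float)
    for (group, label), vals in cells.items():
        mat.loc[group, label] = float(np.mean(vals))
    if n_missing:
        log.info("expression_methylation_matrix: %d genes without "
                 "expression values excluded", n_missing)
    return mat, n_missing


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def delta_delta_regression(gene_table: pd.DataFrame) -> RegressionResult:
    """OLS fit of expression change on methylation change across genes.

    ``gene_table`` needs columns delta_meth and delta_expr; non-finite rows
    are dropped.  Returns the slope, intercept, Pearson r and the two-sided
    p-value for slope != 0.
    """
    x = gene_table["delta_meth"].to_numpy(float)
    y = gene_table["delta_expr"].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 genes with finite values")
    if np.ptp(x) == 0:
        raise ValueError("delta_meth has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r=float(fit.rvalue), p_value=float(fit.pvalue),
                            n=len(x))
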