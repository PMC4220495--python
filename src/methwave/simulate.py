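"""Synthetic methylomes, gene models, expression and ChIP reads with truth.

The generator emulates the statistical structure the pipeline cares about,
not real genome sequence: CpG positions follow a two-state (island/desert)
spacing process so the gap rule is exercised; per-CpG coverage is
negative-binomial (overdispersed, like WGBS depth); methylated read counts
are binomial around region-level true methylation; planted DMRs lower one
sample's true level by a known delta inside known spans.  Matched null
regions with no planted difference make precision measurable.  Every output
is a deterministic function of the config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import Dmr, GeneModel, GenomicInterval, MethylomeTrack

# independent deterministic random streams per generator
_STREAM_METH = 0
_STREAM_GENES = 1
_STREAM_CHIP = 2
_STREAM_EXPR = 3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults model one 5 Mb chromosome at 30x mean coverage with a CpG
    every ~100 bp on average, an 80% methylated baseline in both samples,
    and 50 planted DMRs of delta 0.5 spanning 8-15 CpGs alongside 50
    matched null regions.
    """

    seed: int = 1
    n_chroms: int = 1
    chrom_len_bp: int = 5_000_000

    # CpG spacing: island/desert two-state process (gap means in bp,
    # switching probabilities per CpG)
    island_gap_mean_bp: float = 20.0
    desert_gap_mean_bp: float = 120.0
    p_enter_island: float = 0.01
    p_exit_island: float = 0.05

    # sequencing depth
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0   # negative-binomial size; larger = tighter
    dropout_fraction: float = 0.05     # CpGs missing per sample, independently

    # methylation model
    baseline_level_a: float = 0.8
    baseline_level_b: float = 0.8

    # planted differential regions (auto-placed unless given explicitly)
    n_planted_dmrs: int = 50
    n_null_regions: int = 50
    planted_delta: float = 0.5
    planted_cpg_min: int = 8
    planted_cpg_max: int = 15
    hyper_fraction: float = 0.2        # share of planted DMRs where B drops
    max_planted_gap_bp: int = 1000     # planted runs keep internal gaps below this
    min_region_sep_cpgs: int = 25
    planted_dmrs: Optional[tuple[tuple[str, int, int, float, str], ...]] = None
    # explicit spans: (chrom, start, end, delta, direction)

    # gene models
    n_genes: int = 20
    gene_len_min_bp: int = 2000
    gene_len_max_bp: int = 20000
    max_exons: int = 6
    gene_over_dmr_fractions: tuple[float, ...] = (0.3, 0.1)

    # ChIP model
    n_input_reads: int = 50000
    n_chip_reads: int = 50000
    read_len_bp: int = 50
    n_enriched_regions: int = 10
    enriched_len_bp: int = 2000
    enriched_fold: float = 4.0
    planted_enriched_regions: Optional[tuple[tuple[str, int, int, float], ...]] = None

    # expression model: log2 fold change = slope * gene-body delta + noise,
    # around a log-normal baseline FPKM
    fpkm_log_mean: float = 1.0
    fpkm_log_sd: float = 1.5
    expr_slope_per_delta: float = -4.0
    expr_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.chrom_len_bp <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        for lv in (self.baseline_level_a, self.baseline_level_b):
            if not 0 <= lv <= 1:
                raise ValueError("baseline level outside [0, 1]")
        if not 0 < self.planted_delta <= 1:
            raise ValueError("planted_delta must be in (0, 1]")
        if self.planted_cpg_min < 2 or self.planted_cpg_max < self.planted_cpg_min:
            raise ValueError("bad planted CpG range")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_len_bp for c in self.chrom_names()}


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    delta: float      # signed, sample A minus sample B; 0 for null regions
    direction: str    # hyper | hypo | null
    n_cpgs: int = 0


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    covered_fraction: float
    direction: str


@dataclass(frozen=True)
class TruthTable:
    """Ground truth written alongside every simulated dataset."""

    dmrs: tuple[PlantedRegion, ...] = ()
    null_regions: tuple[PlantedRegion, ...] = ()
    genes: tuple[PlantedGene, ...] = ()
    enriched_regions: tuple[tuple[GenomicInterval, float], ...] = ()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _cpg_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Clustered CpG positions on one chromosome via the island/desert
    spacing process.  Gaps are >= 2 bp so dinucleotides never overlap."""
    positions = []
    pos = 0
    in_island = False
    # sample state-run lengths and gaps in blocks for speed
    while pos < config.chrom_len_bp - 2:
        p_switch = config.p_exit_island if in_island else config.p_enter_island
        run = int(rng.geometric(p_switch))
        mean_gap = (config.island_gap_mean_bp if in_island
                    else config.desert_gap_mean_bp)
        gaps = 2 + rng.geometric(1.0 / max(mean_gap - 2, 1.0), size=run)
        block = pos + np.cumsum(gaps)
        block = block[block < config.chrom_len_bp - 2]
        positions.append(block)
        if not len(block):
            break
        pos = int(block[-1])
        in_island = not in_island
    return np.concatenate(positions) if positions else np.empty(0, np.int64)


def _auto_plant(config: SimConfig, pos_by_chrom: dict[str, np.ndarray],
                rng: np.random.Generator
                ) -> tuple[list[PlantedRegion], list[PlantedRegion]]:
    """Place planted DMRs and null regions on non-overlapping CpG runs whose
    internal gaps stay within the gap limit (a run broken by a longer gap is
    by definition not one contiguous region)."""
    n_regions = config.n_planted_dmrs + config.n_null_regions
    chroms = list(pos_by_chrom)
    quota = {c: n_regions // len(chroms) + (i < n_regions % len(chroms))
             for i, c in enumerate(chroms)}
    slots: list[tuple[str, int, int]] = []   # (chrom, i_start, n_cpgs)
    for chrom in chroms:
        pos = pos_by_chrom[chrom]
        n = len(pos)
        taken = np.zeros(n, dtype=bool)
        want = quota[chrom]
        attempts = 0
        got = 0
        while got < want and attempts < 200 * want:
            attempts += 1
            k = int(rng.integers(config.planted_cpg_min,
                                 config.planted_cpg_max + 1))
            i = int(rng.integers(0, max(1, n - k)))
            sep = config.min_region_sep_cpgs
            lo, hi = max(0, i - sep), min(n, i + k + sep)
            if taken[lo:hi].any():
                continue
            if np.diff(pos[i:i + k]).max() >= config.max_planted_gap_bp:
                continue
            taken[lo:hi] = True
            slots.append((chrom, i, k))
            got += 1
        if got < want:
            raise ValueError(
                f"could not place {want} regions on {chrom}; "
                "genome too small or too sparse"
            )
    rng.shuffle(slots)
    dmrs, nulls = [], []
    for idx, (chrom, i, k) in enumerate(slots):
        pos = pos_by_chrom[chrom]
        span = (int(pos[i]), int(pos[i + k - 1]) + 2)
        if idx < config.n_planted_dmrs:
            hyper = rng.random() < config.hyper_fraction
            delta = config.planted_delta if hyper else -config.planted_delta
            dmrs.append(PlantedRegion(chrom, *span, delta=delta,
                                      direction="hyper" if hyper else "hypo",
                                      n_cpgs=k))
        else:
            nulls.append(PlantedRegion(chrom, *span, delta=0.0,
                                       direction="null", n_cpgs=k))
    return dmrs, nulls


def _explicit_planted(config: SimConfig) -> list[PlantedRegion]:
    out = []
    for chrom, start, end, delta, direction in config.planted_dmrs:
        if start < 0 or end > config.chrom_len_bp:
            raise ValueError(
                f"planted DMR {chrom}:{start}-{end} outside chromosome"
            )
        out.append(PlantedRegion(chrom, start, end,
                                 delta=delta if direction == "hyper" else -abs(delta),
                                 direction=direction))
    return out


def simulate_methylome_pair(config: SimConfig = SimConfig()
                            ) -> tuple[MethylomeTrack, MethylomeTrack, TruthTable]:
    """Simulate a pair of high-coverage CpG tracks with planted DMRs.

    True levels are the sample baselines outside planted regions; inside a
    hypo region sample A's level drops by |delta|, inside a hyper region
    sample B's drops (so delta = A - B keeps the stated sign).  Observed
    levels are binomial draws at negative-binomial coverage; each sample
    independently loses a dropout fraction of sites, and zero-coverage
    sites are dropped like in real calls.
    """
    rng = _rng(config, _STREAM_METH)
    pos_by_chrom = {c: _cpg_positions(config, rng)
                    for c in config.chrom_names()}
    if config.planted_dmrs is not None:
        dmrs = _explicit_planted(config)
        nulls: list[PlantedRegion] = []
    else:
        dmrs, nulls = _auto_plant(config, pos_by_chrom, rng)

    frames_a, frames_b = [], []
    for chrom in config.chrom_names():
        pos = pos_by_chrom[chrom]
        n = len(pos)
        level_a = np.full(n, config.baseline_level_a)
        level_b = np.full(n, config.baseline_level_b)
        for r in dmrs:
            if r.chrom != chrom:
                continue
            inside = (pos >= r.start) & (pos < r.end)
            if r.delta < 0:
                level_a[inside] = config.baseline_level_a - abs(r.delta)
            else:
                level_b[inside] = config.baseline_level_b - abs(r.delta)
        level_a = np.clip(level_a, 0.0, 1.0)
        level_b = np.clip(level_b, 0.0, 1.0)
        p_nb = config.coverage_dispersion / (config.coverage_dispersion
                                             + config.coverage_mean)
        for levels, frames in ((level_a, frames_a), (level_b, frames_b)):
            cov = rng.negative_binomial(config.coverage_dispersion, p_nb, size=n)
            keep = (cov > 0) & (rng.random(n) >= config.dropout_fraction)
            meth = rng.binomial(cov[keep], levels[keep])
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos[keep],
                "level": meth / cov[keep], "coverage": cov[keep],
            }))
    track_a = MethylomeTrack(pd.concat(frames_a, ignore_index=True))
    track_b = MethylomeTrack(pd.concat(frames_b, ignore_index=True))
    truth = TruthTable(dmrs=tuple(dmrs), null_regions=tuple(nulls))
    return track_a, track_b, truth


def _split_exons(chrom: str, start: int, end: int, n_exons: int,
                 rng: np.random.Generator) -> tuple[GenomicInterval, ...]:
    """First/last exons pinned to the gene ends; internal boundaries drawn
    at random even positions."""
    if n_exons == 1:
        return (GenomicInterval(chrom, start, end),)
    cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_exons - 1),
                              replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple(
        GenomicInterval(chrom, bounds[2 * k], bounds[2 * k + 1])
        for k in range(n_exons)
    )


def simulate_gene_models(config: SimConfig = SimConfig(),
                         truth: Optional[TruthTable] = None,
                         ) -> tuple[list[GeneModel], TruthTable]:
    """Simulate non-overlapping stranded genes with exon structure.

    If planted-DMR truth is given, the first genes are constructed over
    planted DMRs with covered fractions cycling through
    ``gene_over_dmr_fractions``, so gene-body calls are known by
    construction; the rest land in free space with no planted signal.
    """
    rng = _rng(config, _STREAM_GENES)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names()}
    genes: list[GeneModel] = []
    planted_genes: list[PlantedGene] = []
    planted = list(truth.dmrs) if truth is not None else []
    for r in truth.null_regions if truth is not None else ():
        occupied[r.chrom].append((r.start, r.end))

    def free(chrom: str, s: int, e: int) -> bool:
        return (0 <= s and e <= config.chrom_len_bp
                and not any(s < oe and os_ < e for os_, oe in occupied[chrom]))

    k = 0
    for gi in range(config.n_genes):
        gid = f"gene_{gi + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        if k < len(planted) and k < len(planted):
            r = planted[k]
            frac = config.gene_over_dmr_fractions[
                k % len(config.gene_over_dmr_fractions)]
            span = r.end - r.start
            glen = int(round(span / frac))
            s = r.start - int(rng.integers(0, max(1, glen - span)))
            s = max(0, min(s, config.chrom_len_bp - glen))
            e = s + glen
            if free(r.chrom, s - 1000, e + 1000) and s <= r.start and e >= r.end:
                n_ex = int(rng.integers(1, config.max_exons + 1))
                genes.append(GeneModel(
                    gene_id=gid, chrom=r.chrom, strand=strand, start=s, end=e,
                    exons=_split_exons(r.chrom, s, e, n_ex, rng)))
                occupied[r.chrom].append((s, e))
                planted_genes.append(PlantedGene(
                    gene_id=gid, covered_fraction=span / glen,
                    direction=r.direction))
                k += 1
                placed = True
        if not placed:
            for _ in range(500):
                chrom = config.chrom_names()[int(rng.integers(config.n_chroms))]
                glen = int(rng.integers(config.gene_len_min_bp,
                                        config.gene_len_max_bp + 1))
                s = int(rng.integers(0, max(1, config.chrom_len_bp - glen)))
                if free(chrom, s - 1000, s + glen + 1000):
                    n_ex = int(rng.integers(1, config.max_exons + 1))
                    genes.append(GeneModel(
                        gene_id=gid, chrom=chrom, strand=strand,
                        start=s, end=s + glen,
                        exons=_split_exons(chrom, s, s + glen, n_ex, rng)))
                    occupied[chrom].append((s, s + glen))
                    planted_genes.append(PlantedGene(
                        gene_id=gid, covered_fraction=0.0, direction="none"))
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place gene; genome too crowded")
    genes.sort(key=lambda g: (g.chrom, g.start))
    new_truth = replace(truth if truth is not None else TruthTable(),
                        genes=tuple(planted_genes))
    return genes, new_truth


def simulate_chip(config: SimConfig = SimConfig(),
                  ) -> tuple[list[GenomicInterval], list[GenomicInterval], TruthTable]:
    """Simulate ChIP and input read piles.

    Input reads start uniformly over the genome; ChIP read starts are drawn
    with density multiplied by ``enriched_fold`` inside planted enriched
    regions.  Returns (chip_reads, input_reads, truth).
    """
    rng = _rng(config, _STREAM_CHIP)
    sizes = config.chrom_sizes()
    if config.planted_enriched_regions is not None:
        regions = [(GenomicInterval(c, s, e), f)
                   for c, s, e, f in config.planted_enriched_regions]
    else:
        regions = []
        for j in range(config.n_enriched_regions):
            chrom = config.chrom_names()[j % config.n_chroms]
            s = int(rng.integers(0, config.chrom_len_bp - config.enriched_len_bp))
            regions.append((GenomicInterval(chrom, s, s + config.enriched_len_bp),
                            config.enriched_fold))

    def uniform_reads(n: int) -> list[GenomicInterval]:
        out = []
        chroms = config.chrom_names()
        counts = rng.multinomial(n, [1 / len(chroms)] * len(chroms))
        for chrom, cnt in zip(chroms, counts):
            starts = rng.integers(0, sizes[chrom] - config.read_len_bp, size=cnt)
            out += [GenomicInterval(chrom, int(s), int(s) + config.read_len_bp,
                                    strand="+")
                    for s in np.sort(starts)]
        return out

    input_reads = uniform_reads(config.n_input_reads)

    # ChIP: a uniform genome-wide component plus (fold-1)-weighted extra
    # reads inside each region, so in-region density is fold times baseline
    genome_len = sum(sizes.values())
    weights = [float(genome_len)] + [iv.length * (f - 1.0) for iv, f in regions]
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    alloc = rng.multinomial(config.n_chip_reads, probs)
    chip_reads = uniform_reads(int(alloc[0]))
    for (iv, _), cnt in zip(regions, alloc[1:]):
        starts = rng.integers(iv.start, max(iv.start + 1,
                                            iv.end - config.read_len_bp),
                              size=int(cnt))
        chip_reads += [GenomicInterval(iv.chrom, int(s),
                                       int(s) + config.read_len_bp, strand="+")
                       for s in np.sort(starts)]
    chip_reads.sort(key=lambda r: (r.chrom, r.start))
    return chip_reads, input_reads, TruthTable(enriched_regions=tuple(regions))


def simulate_expression(genes: Sequence[GeneModel], truth: TruthTable,
                        config: SimConfig = SimConfig()) -> pd.DataFrame:
    """Per-gene FPKM in two conditions, coupled to planted gene-body
    methylation: log2(FPKM_a / FPKM_b) = slope * (gene-body delta) + noise.

    The gene-body delta is the planted delta scaled by the constructed
    covered fraction (0 for genes without planted signal).
    """
    rng = _rng(config, _STREAM_EXPR)
    frac = {g.gene_id: g.covered_fraction for g in truth.genes}
    direc = {g.gene_id: g.direction for g in truth.genes}
    rows = []
    for g in genes:
        body_delta = 0.0
        if direc.get(g.gene_id) in ("hyper", "hypo"):
            sign = 1.0 if direc[g.gene_id] == "hyper" else -1.0
            body_delta = sign * config.planted_delta * frac[g.gene_id]
        fpkm_b = float(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd))
        log2fc = (config.expr_slope_per_delta * body_delta
                  + rng.normal(0.0, config.expr_noise_sd))
        rows.append({"gene_id": g.gene_id,
                     "fpkm_a": fpkm_b * 2.0 ** log2fc,
                     "fpkm_b": fpkm_b,
                     "true_body_delta": body_delta})
    return pd.DataFrame(rows)


# --- recovery evaluation ---------------------------------------------------

RECOVERY_OVERLAP_FRACTION = 0.5


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def evaluate_recovery(called: Sequence[Dmr], truth: TruthTable
                      ) -> dict[str, float]:
    """Overlap-based sensitivity and precision against planted truth.

    A planted DMR is found iff some called DMR covers at least half of its
    span; a called DMR is a true positive by the same rule.  Null-region
    hits are counted separately.
    """
    found = 0
    for r in truth.dmrs:
        span = r.end - r.start
        if any(d.chrom == r.chrom
               and _overlap(d.start, d.end, r.start, r.end) >= RECOVERY_OVERLAP_FRACTION * span
               for d in called):
            found += 1
    tp = 0
    null_hits = 0
    for d in called:
        if any(r.chrom == d.chrom
               and _overlap(d.start, d.end, r.start, r.end)
               >= RECOVERY_OVERLAP_FRACTION * (r.end - r.start)
               for r in truth.dmrs):
            tp += 1
        if any(r.chrom == d.chrom
               and _overlap(d.start, d.end, r.start, r.end) > 0
               for r in truth.null_regions):
            null_hits += 1
    sens = found / len(truth.dmrs) if truth.dmrs else float("nan")
    prec = tp / len(called) if called else float("nan")
    return {"sensitivity": sens, "precision": prec,
            "n_called": float(len(called)), "null_hits": float(null_hits)}


# --- truth serialization ---------------------------------------------------

def write_truth(truth: TruthTable, path) -> None:
    """Write planted regions/genes as a tidy TSV truth table."""
    rows = []
    for r in list(truth.dmrs) + list(truth.null_regions):
        rows.append({"kind": "region", "id": f"{r.chrom}:{r.start}-{r.end}",
                     "chrom": r.chrom, "start": r.start, "end": r.end,
                     "value": r.delta, "label": r.direction})
    for g in truth.genes:
        rows.append({"kind": "gene", "id": g.gene_id, "chrom": "", "start": -1,
                     "end": -1, "value": g.covered_fraction,
                     "label": g.direction})
    for iv, fold in truth.enriched_regions:
        rows.append({"kind": "enriched", "id": f"{iv.chrom}:{iv.start}-{iv.end}",
                     "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "value": fold, "label": "enriched"})
    pd.DataFrame(rows, columns=["kind", "id", "chrom", "start", "end",
                                "value", "label"]).to_csv(path, sep="\t",
                                                          index=False)


def write_bismark_cov(track: MethylomeTrack, path) -> None:
    """Write a track in Bismark coverage format (1-based inclusive)."""
    df = track.df
    n_meth = np.rint(df["level"] * df["coverage"]).astype(np.int64)
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"] + 1,
        "end": df["pos"] + 1,
        "pct": np.where(df["coverage"] > 0,
                        100.0 * n_meth / df["coverage"].clip(lower=1), 0.0),
        "n_meth": n_meth,
        "n_unmeth": df["coverage"] - n_meth,
    })
    out.to_csv(path, sep="\t", index=False, header=False,
               float_format="%.4f")
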