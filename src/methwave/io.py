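"""Readers and writers for the on-disk formats the pipeline consumes.

Every reader normalizes to the internal 0-based half-open convention;
writers restore each format's native convention for integer fields.
Bismark coverage files are treated as 1-based inclusive (start == end for a
single cytosine); BED and bedGraph are already 0-based half-open; GTF is
1-based inclusive.
"""
from __future__ import annotations

import io as _io
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (Dmr, GeneModel, GenomicInterval, MethylomeTrack,
                    PairedTrack, TRACK_COLUMNS, PAIRED_COLUMNS, make_dmr)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def _read_table(path: PathLike, names: Sequence[str], numeric: Sequence[str],
                comment: str = "#") -> pd.DataFrame:
    """Whitespace-delimited table reader with per-line error reporting."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment=comment,
                     names=list(names), dtype=str, skip_blank_lines=False)
    df = df.dropna(how="all")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            bad_idx = int((bad | df[col].isna()).idxmax())
            raise ParseError(
                f"{path}: malformed line {bad_idx + 1}: "
                f"cannot parse column {col!r}"
            )
        df[col] = converted
    return df.reset_index(drop=True)


def read_bismark_cov(path: PathLike) -> MethylomeTrack:
    """Read a Bismark coverage file into a :class:`MethylomeTrack`.

    Columns: chrom, start (1-based), end, methylation %, count methylated,
    count unmethylated.  The stored level is recomputed from the counts;
    a stated percentage disagreeing with the counts by more than 0.5
    percentage points triggers a warning and the counts win.  Rows with zero
    total coverage are dropped.
    """
    names = ["chrom", "start", "end", "pct", "n_meth", "n_unmeth"]
    df = _read_table(path, names, numeric=names[1:])
    if not len(df):
        return MethylomeTrack.empty()
    total = df["n_meth"] + df["n_unmeth"]
    df = df[total > 0].copy()
    total = total[total > 0]
    if not len(df):
        return MethylomeTrack.empty()
    level = df["n_meth"] / total
    mism = (level * 100 - df["pct"]).abs() > 0.5
    if mism.any():
        warnings.warn(
            f"{path}: {int(mism.sum())} rows where stated methylation % "
            "disagrees with counts by >0.5 points; counts win",
            stacklevel=2,
        )
    return MethylomeTrack(pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(np.int64) - 1,
        "level": level,
        "coverage": total.astype(np.int64),
    }))


def read_bedgraph(path: PathLike) -> MethylomeTrack:
    """Read a 4-column methylation bedGraph (value in % or fraction).

    Values above 1 anywhere mark the file as percent-scaled.  bedGraph
    carries no read depth, so coverage is recorded as 0 (unknown); do not
    coverage-filter such tracks.
    """
    names = ["chrom", "start", "end", "value"]
    with open(path) as fh:
        body = "".join(
            line for line in fh
            if not line.startswith(("track", "browser", "#"))
        )
    df = _read_table(_io.StringIO(body), names, numeric=names[1:])
    if not len(df):
        return MethylomeTrack.empty()
    value = df["value"].to_numpy(float)
    if np.nanmax(value) > 1.0:
        value = value / 100.0
    return MethylomeTrack(pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(np.int64),
        "level": value,
        "coverage": 0,
    }))


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3-6 into intervals."""
    raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str,
                      skip_blank_lines=True)
    out: list[GenomicInterval] = []
    for i, row in raw.iterrows():
        vals = [v for v in row.tolist() if isinstance(v, str)]
        if vals and vals[0] in ("track", "browser"):
            continue
        try:
            chrom, start, end = vals[0], int(vals[1]), int(vals[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed line {i + 1}: {exc}") from exc
        name = vals[3] if len(vals) > 3 else None
        score = None
        if len(vals) > 4 and vals[4] not in (".", ""):
            score = float(vals[4])
        strand = vals[5] if len(vals) > 5 and vals[5] in ("+", "-") else None
        out.append(GenomicInterval(chrom, start, end, strand=strand,
                                   name=name, score=score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), iv.name or ".",
                "0" if iv.score is None else f"{iv.score:g}",
                iv.strand or ".",
            ]) + "\n")


def read_bed12(path: PathLike) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons, thick region CDS)."""
    names = ["chrom", "start", "end", "name", "score", "strand",
             "thick_start", "thick_end", "rgb", "n_blocks",
             "block_sizes", "block_starts"]
    raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                      names=names, dtype=str)
    genes: list[GeneModel] = []
    for i, row in raw.iterrows():
        try:
            chrom = row["chrom"]
            start, end = int(row["start"]), int(row["end"])
            strand = row["strand"]
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand {strand!r}")
            sizes = [int(x) for x in row["block_sizes"].rstrip(",").split(",")]
            offs = [int(x) for x in row["block_starts"].rstrip(",").split(",")]
            if len(sizes) != int(row["n_blocks"]) or len(sizes) != len(offs):
                raise ValueError("block count mismatch")
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s)
                for o, s in sorted(zip(offs, sizes))
            )
            thick_start, thick_end = int(row["thick_start"]), int(row["thick_end"])
            cds = (thick_start, thick_end) if thick_end > thick_start else (None, None)
            genes.append(GeneModel(
                gene_id=row["name"], chrom=chrom, strand=strand,
                start=start, end=end, exons=exons,
                cds_start=cds[0], cds_end=cds[1],
            ))
        except (ValueError, AttributeError) as exc:
            raise ParseError(f"{path}: malformed line {i + 1}: {exc}") from exc
    return genes


def write_bed12(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length) for e in g.exons) + ","
            offs = ",".join(str(e.start - g.start) for e in g.exons) + ","
            thick = (g.cds_start, g.cds_end) if g.cds_start is not None else (g.start, g.start)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                thick[0], thick[1], 0, len(g.exons), sizes, offs,
            ])) + "\n")


def read_gtf(path: PathLike) -> list[GeneModel]:
    """Read gene models from GTF: exon features grouped by gene_id, with
    optional CDS features defining the thick (coding) region."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ParseError(f"{path}: {feat.featuretype} without gene_id")
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {gid}: unknown strand {feat.strand!r}")
        meta.setdefault(gid, (feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        # GTF is 1-based inclusive
        target.setdefault(gid, []).append((feat.start - 1, feat.end))
    genes = []
    for gid, (chrom, strand) in meta.items():
        ex = sorted(exons.get(gid, []))
        if not ex:
            raise ParseError(f"{path}: gene {gid} has no exons")
        merged = _merge_intervals(ex)
        cds_iv = cds.get(gid)
        cstart = min(s for s, _ in cds_iv) if cds_iv else None
        cend = max(e for _, e in cds_iv) if cds_iv else None
        genes.append(GeneModel(
            gene_id=gid, chrom=chrom, strand=strand,
            start=merged[0][0], end=merged[-1][1],
            exons=tuple(GenomicInterval(chrom, s, e) for s, e in merged),
            cds_start=cstart, cds_end=cend,
        ))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def read_gene_models(path: PathLike, format: Optional[str] = None) -> list[GeneModel]:
    """Dispatch on ``format`` ("gtf" or "bed12"), inferred from suffix if None."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "gtf" if suffix in (".gtf", ".gff") else "bed12"
    if format == "gtf":
        return read_gtf(path)
    if format == "bed12":
        return read_bed12(path)
    raise ValueError(f"unknown gene model format {format!r}")


DMR_HEADER = "#chrom\tstart\tend\tname\tn_cpgs\tdirection\tmean_delta\tcpg_positions"


def write_dmrs(dmrs: Iterable[Dmr], path: PathLike) -> None:
    """Write DMRs as BED6+ (chrom, start, end, name, n_cpgs, direction,
    mean_delta, comma-joined member CpG positions)."""
    with open(path, "w") as fh:
        fh.write(DMR_HEADER + "\n")
        for d in dmrs:
            fh.write("\t".join([
                d.chrom, str(d.start), str(d.end), d.dmr_id, str(d.n_cpgs),
                d.direction, f"{d.mean_delta:.6f}",
                ",".join(str(p) for p in d.cpg_positions),
            ]) + "\n")


def read_dmrs(path: PathLike) -> list[Dmr]:
    out: list[Dmr] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                chrom, start, end, name, n_cpgs, direction, mean_delta, pos = \
                    line.rstrip("\n").split("\t")
                positions = tuple(int(p) for p in pos.split(","))
                d = Dmr(chrom=chrom, start=int(start), end=int(end),
                        cpg_positions=positions, direction=direction,
                        mean_delta=float(mean_delta), name=name)
                if d.n_cpgs != int(n_cpgs):
                    raise ValueError("n_cpgs column disagrees with positions")
            except ValueError as exc:
                raise ParseError(f"{path}: malformed line {i}: {exc}") from exc
            out.append(d)
    return out


def write_track(track: MethylomeTrack, path: PathLike,
                smoothed: Optional[np.ndarray] = None) -> None:
    """Write a track as TSV: chrom, pos, level, smoothed, coverage."""
    df = track.df.copy()
    df["smoothed"] = df["level"] if smoothed is None else smoothed
    df = df[["chrom", "pos", "level", "smoothed", "coverage"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_track(path: PathLike, use_smoothed: bool = False) -> MethylomeTrack:
    df = pd.read_csv(path, sep="\t")
    level = df["smoothed"] if use_smoothed and "smoothed" in df else df["level"]
    return MethylomeTrack(pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"],
        "level": level, "coverage": df.get("coverage", 0),
    }))


def write_paired_track(paired: PairedTrack, path: PathLike) -> None:
    paired.df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_paired_track(path: PathLike) -> PairedTrack:
    return PairedTrack(pd.read_csv(path, sep="\t"))


CHR_PREFIX = "chr"


def add_chrom_prefix(name: str) -> str:
    return name if name.startswith(CHR_PREFIX) else CHR_PREFIX + name


def strip_chrom_prefix(name: str) -> str:
    return name[len(CHR_PREFIX):] if name.startswith(CHR_PREFIX) else name


def harmonize_chrom_names(names: Iterable[str], style: str = "chr") -> list[str]:
    """Map chromosome names to a single naming style ("chr" or "plain").

    Chromosome names are otherwise matched exactly; this explicit remapping is
    the only aliasing the pipeline performs.
    """
    fn = add_chrom_prefix if style == "chr" else strip_chrom_prefix
    return [fn(n) for n in names]
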