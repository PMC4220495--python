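"""Core data model: CpG calls, methylome tracks, intervals, genes and DMRs.

All coordinates are 0-based half-open internally.  A CpG site is keyed by the
position of the C on the plus strand; a minus-strand call at position ``p``
(the G of the palindromic dinucleotide) belongs to site ``p - 1``.
Methylation levels are fractions in ``[0, 1]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

TRACK_COLUMNS = ["chrom", "pos", "level", "coverage"]
PAIRED_COLUMNS = [
    "chrom", "pos", "level_a", "level_b", "smoothed_a", "smoothed_b", "delta",
]


@dataclass(frozen=True)
class CpGCall:
    """A single stranded cytosine methylation call.

    ``pos`` is the 0-based position of the called cytosine itself, i.e. the C
    on the plus strand or the G-paired C on the minus strand.
    """

    chrom: str
    pos: int
    strand: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]"
            )
        if self.site < 0:
            raise ValueError("minus-strand call at position 0 has no CpG site")

    @property
    def site(self) -> int:
        """Plus-strand C position of the CpG dinucleotide this call covers."""
        return self.pos if self.strand == "+" else self.pos - 1

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded/named/scored."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon structure.

    ``start``/``end`` are the genomic span (0-based half-open).  The TSS/TES
    are derived from the strand: on minus-strand genes the TSS is the last
    base of the span (``end - 1``) and the TES the first (``start``).
    ``cds_start``/``cds_end`` (genomic, strand-agnostic) enable UTR-level
    annotation; without them UTRs are indistinguishable from exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[GenomicInterval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: empty span")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.start or ex.end > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return tuple(out)

    def exons_5to3(self) -> tuple[GenomicInterval, ...]:
        """Exons ordered in transcription direction."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns_5to3(self) -> tuple[GenomicInterval, ...]:
        return self.introns if self.strand == "+" else tuple(reversed(self.introns))


def _as_track_frame(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing track columns: {missing}")
    df = df.loc[:, list(columns)].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for c in columns:
        if c in ("chrom", "pos"):
            continue
        df[c] = df[c].astype(np.int64 if c == "coverage" else np.float64)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate CpG position {first['chrom']}:{first['pos']}"
        )
    if (df["pos"] < 0).any():
        raise ValueError("negative CpG position")
    return df


class MethylomeTrack:
    """Sorted per-CpG methylation levels with coverage for one sample.

    Backed by a DataFrame with columns chrom, pos, level, coverage, sorted by
    (chrom, pos) with unique positions and levels in [0, 1].
    """

    def __init__(self, df: pd.DataFrame):
        df = _as_track_frame(df, TRACK_COLUMNS)
        if ((df["level"] < 0) | (df["level"] > 1)).any():
            raise ValueError("methylation level outside [0, 1]")
        if (df["coverage"] < 0).any():
            raise ValueError("negative coverage")
        self.df = df

    @classmethod
    def from_arrays(cls, chrom, pos, level, coverage) -> "MethylomeTrack":
        return cls(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "level": level, "coverage": coverage}
        ))

    @classmethod
    def empty(cls) -> "MethylomeTrack":
        return cls(pd.DataFrame({c: [] for c in TRACK_COLUMNS}))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def per_chrom(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def total_coverage(self) -> int:
        return int(self.df["coverage"].sum())

    def equals(self, other: "MethylomeTrack", level_decimals: int = 6) -> bool:
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        return (
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["pos"].to_numpy() == b["pos"].to_numpy()).all()
            and (a["coverage"].to_numpy() == b["coverage"].to_numpy()).all()
            and np.allclose(a["level"], b["level"], atol=0.5 * 10 ** -level_decimals)
        )


class PairedTrack:
    """CpGs shared by two samples with smoothed levels and per-CpG delta.

    delta = smoothed_a - smoothed_b, so positive deltas mean sample A is
    hypermethylated relative to sample B at that site.
    """

    def __init__(self, df: pd.DataFrame):
        df = _as_track_frame(df, PAIRED_COLUMNS)
        if len(df):
            resid = df["delta"] - (df["smoothed_a"] - df["smoothed_b"])
            if np.abs(resid).max() > 1e-9:
                raise ValueError("delta != smoothed_a - smoothed_b")
            if np.abs(df["delta"]).max() > 1 + 1e-12:
                raise ValueError("delta outside [-1, 1]")
        self.df = df

    @classmethod
    def empty(cls) -> "PairedTrack":
        return cls(pd.DataFrame({c: [] for c in PAIRED_COLUMNS}))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def per_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (chrom, positions, deltas) per chromosome."""
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub["pos"].to_numpy(), sub["delta"].to_numpy()

    def swapped(self) -> "PairedTrack":
        """The same pairing with samples A and B exchanged."""
        df = self.df.rename(columns={
            "level_a": "level_b", "level_b": "level_a",
            "smoothed_a": "smoothed_b", "smoothed_b": "smoothed_a",
        }).copy()
        df["delta"] = -df["delta"]
        return PairedTrack(df[PAIRED_COLUMNS])


# span of the reported DMR runs from the first member C to the end of the
# last member dinucleotide (last C + 2)
DMR_END_PAD = 2


@dataclass(frozen=True)
class Dmr:
    """A maximal differentially methylated region between two samples.

    ``direction`` follows the sign of delta (sample A minus sample B):
    "hyper" when A is more methylated, "hypo" when less.
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    direction: str
    mean_delta: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not self.cpg_positions:
            raise ValueError("DMR with no CpGs")
        pos = np.asarray(self.cpg_positions)
        if (np.diff(pos) <= 0).any():
            raise ValueError("CpG positions not strictly increasing")
        if self.start != self.cpg_positions[0]:
            raise ValueError("DMR start must equal first member CpG position")
        if self.end != self.cpg_positions[-1] + DMR_END_PAD:
            raise ValueError("DMR end must equal last member CpG + 2")
        if self.direction == "hyper" and self.mean_delta <= 0:
            raise ValueError("hyper DMR with non-positive mean delta")
        if self.direction == "hypo" and self.mean_delta >= 0:
            raise ValueError("hypo DMR with non-negative mean delta")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dmr_id(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.dmr_id)


def make_dmr(chrom: str, positions: Sequence[int], mean_delta: float,
             name: str = "") -> Dmr:
    """Build a Dmr from member CpG positions using the span convention."""
    positions = tuple(int(p) for p in positions)
    direction = "hyper" if mean_delta > 0 else "hypo"
    return Dmr(chrom=chrom, start=positions[0], end=positions[-1] + DMR_END_PAD,
               cpg_positions=positions, direction=direction,
               mean_delta=float(mean_delta), name=name)
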