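"""Turn raw CpG calls into analysis-ready tracks.

Pipeline order: combine strands -> mask -> coverage filter -> intersect the
two samples -> smooth.  Mask and coverage filtering commute; smoothing is
applied to the intersected common-CpG grid by default so that both samples
are averaged over the same local CpG index window (a config switch smooths
each full track before intersection instead).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import CpGCall, GenomicInterval, MethylomeTrack, PairedTrack

log = logging.getLogger(__name__)

SMOOTH_AFTER_INTERSECT = "after_intersect"
SMOOTH_BEFORE_INTERSECT = "before_intersect"


@dataclass(frozen=True)
class PreprocessParams:
    """Site-level filters applied before DMR calling.

    min_coverage: minimal combined-strand read depth for a CpG to be kept
        (default 4 reads).
    smooth_window: running-average width in CpGs, odd (default 3).
    smooth_order: whether smoothing runs on the intersected common grid
        (default) or on each full track before intersection.
    """

    min_coverage: int = 4
    smooth_window: int = 3
    smooth_order: str = SMOOTH_AFTER_INTERSECT

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.smooth_order not in (SMOOTH_AFTER_INTERSECT,
                                     SMOOTH_BEFORE_INTERSECT):
            raise ValueError(f"bad smooth_order {self.smooth_order!r}")


def combine_strands(calls: Iterable[CpGCall]) -> MethylomeTrack:
    """Combine sense and antisense calls of each palindromic CpG site.

    Minus-strand calls at position p are assigned to the plus-strand site
    p - 1; methylated and total counts are summed per site.  A minus-strand
    call with no plus-strand partner still yields its own site (logged).
    """
    calls = list(calls)
    if not calls:
        return MethylomeTrack.empty()
    df = pd.DataFrame({
        "chrom": [c.chrom for c in calls],
        "site": [c.site for c in calls],
        "strand": [c.strand for c in calls],
        "n_meth": [c.meth_count for c in calls],
        "n_total": [c.total_count for c in calls],
    })
    grouped = df.groupby(["chrom", "site"], sort=True).agg(
        n_meth=("n_meth", "sum"),
        n_total=("n_total", "sum"),
        strands=("strand", "nunique"),
        has_plus=("strand", lambda s: (s == "+").any()),
    ).reset_index()
    orphans = int((~grouped["has_plus"]).sum())
    if orphans:
        log.info("combine_strands: %d minus-strand sites without a "
                 "plus-strand call", orphans)
    return MethylomeTrack(pd.DataFrame({
        "chrom": grouped["chrom"],
        "pos": grouped["site"],
        "level": grouped["n_meth"] / grouped["n_total"],
        "coverage": grouped["n_total"],
    }))


def apply_mask(track: MethylomeTrack,
               mask: Sequence[GenomicInterval]) -> MethylomeTrack:
    """Remove CpGs whose site position falls inside any mask interval
    (SNP positions, blacklists).  Intervals are half-open, so a site exactly
    at an interval end is retained."""
    if not len(track) or not mask:
        return MethylomeTrack(track.df)
    trees: dict[str, IntervalTree] = {}
    for iv in mask:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    keep = np.ones(len(track), dtype=bool)
    chroms = track.df["chrom"].to_numpy()
    pos = track.df["pos"].to_numpy()
    for i in range(len(track)):
        tree = trees.get(chroms[i])
        if tree is not None and tree.overlaps_point(int(pos[i])):
            keep[i] = False
    return MethylomeTrack(track.df[keep])


def filter_coverage(track: MethylomeTrack, min_coverage: int = 4) -> MethylomeTrack:
    """Keep CpGs with coverage >= min_coverage (threshold inclusive)."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    return MethylomeTrack(track.df[track.df["coverage"] >= min_coverage])


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running average over ``window`` consecutive entries; at the
    edges the window truncates to the available entries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(values, dtype=float)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def smooth(track: MethylomeTrack, window: int = 3) -> MethylomeTrack:
    """Replace levels by a running average of ``window`` consecutive CpGs.

    Windows are defined in CpG index space (not bp) and never cross
    chromosome boundaries.
    """
    if not len(track):
        return MethylomeTrack(track.df)
    df = track.df.copy()
    df["level"] = (
        df.groupby("chrom", sort=False)["level"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return MethylomeTrack(df)


def intersect_tracks(a: MethylomeTrack, b: MethylomeTrack,
                     smooth_window: int = 3,
                     smooth_order: str = SMOOTH_AFTER_INTERSECT) -> PairedTrack:
    """Pair two tracks on their common CpG positions and compute per-CpG
    smoothed deltas (sample A minus sample B).

    With the default ``smooth_order``, the running average is computed on
    each sample's restriction to the common grid so deltas are differences
    of like-for-like local averages.
    """
    if smooth_order == SMOOTH_BEFORE_INTERSECT:
        a = smooth(a, smooth_window)
        b = smooth(b, smooth_window)
    merged = a.df.merge(b.df, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if not len(merged):
        log.warning("intersect_tracks: no common CpG positions")
        return PairedTrack.empty()
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort")
    if smooth_order == SMOOTH_AFTER_INTERSECT:
        for col in ("level_a", "level_b"):
            merged["smoothed" + col[5:]] = (
                merged.groupby("chrom", sort=False)[col]
                .transform(lambda s: s.rolling(smooth_window, center=True,
                                               min_periods=1).mean())
            )
    else:
        merged["smoothed_a"] = merged["level_a"]
        merged["smoothed_b"] = merged["level_b"]
    merged["delta"] = merged["smoothed_a"] - merged["smoothed_b"]
    return PairedTrack(merged[["chrom", "pos", "level_a", "level_b",
                               "smoothed_a", "smoothed_b", "delta"]])


def pool_tracks(tracks: Sequence[MethylomeTrack]) -> MethylomeTrack:
    """Pool replicate methylomes by summing methylated and total counts per
    site (approximate methylated counts are reconstructed as level*coverage
    rounded to the nearest read)."""
    if not tracks:
        return MethylomeTrack.empty()
    frames = []
    for t in tracks:
        df = t.df.copy()
        df["n_meth"] = np.rint(df["level"] * df["coverage"]).astype(np.int64)
        frames.append(df[["chrom", "pos", "n_meth", "coverage"]])
    allrows = pd.concat(frames, ignore_index=True)
    grouped = allrows.groupby(["chrom", "pos"], sort=True).sum().reset_index()
    return MethylomeTrack(pd.DataFrame({
        "chrom": grouped["chrom"],
        "pos": grouped["pos"],
        "level": grouped["n_meth"] / grouped["coverage"],
        "coverage": grouped["coverage"],
    }))


def preprocess_track(track: MethylomeTrack,
                     mask: Sequence[GenomicInterval] = (),
                     params: PreprocessParams = PreprocessParams()) -> MethylomeTrack:
    """Mask + coverage-filter one combined-strand track (smoothing is left
    to :func:`intersect_tracks`)."""
    return filter_coverage(apply_mask(track, mask), params.min_coverage)
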