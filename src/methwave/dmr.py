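"""Sliding-window DMR detection with extension to maximal qualifying runs.

A DMR between two methylomes is a run of consecutive common CpGs whose
smoothed per-CpG deltas all share one sign, each exceed a per-CpG minimum in
magnitude, sit within a maximal bp gap of their neighbours, and whose mean
delta magnitude exceeds a region-level threshold over at least a seed
window's worth of CpGs.  Candidate seed windows are scanned one CpG at a
time; each is then extended until the criteria fail, i.e. to the maximal
run of CpGs that still satisfies every region criterion and contains a
qualifying seed window.  Because the region mean is not monotone under
extension, "extended until they fail" is implemented as maximal-qualifying-
run semantics rather than one-step greedy growth: a run is reported iff no
strictly larger qualifying run contains it.  Overlapping maximal runs merge
when their union still qualifies; otherwise the longer run wins (ties to
the smaller start), so reported DMRs are disjoint and maximal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .preprocess import SMOOTH_AFTER_INTERSECT, intersect_tracks
from .types import Dmr, MethylomeTrack, PairedTrack, make_dmr

log = logging.getLogger(__name__)

# mean-threshold comparisons tolerate summation-order round-off so that the
# qualifying set does not depend on how the mean was accumulated
MEAN_TOL = 1e-9


@dataclass(frozen=True)
class DmrParams:
    """Thresholds of the window/extension caller.

    mean_delta_min: minimal |mean smoothed delta| over a region, as a
        fraction (default 0.40; the disease comparison accepts 0.20).
    window_cpgs: seed window width in CpGs (default 5).
    per_cpg_delta_min: minimal |smoothed delta| of every member CpG
        (default 0.10).
    max_gap_bp: maximal distance between adjacent member CpGs (default
        1,000 bp).
    """

    mean_delta_min: float = 0.40
    window_cpgs: int = 5
    per_cpg_delta_min: float = 0.10
    max_gap_bp: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.per_cpg_delta_min <= self.mean_delta_min <= 1:
            raise ValueError(
                "need 0 < per_cpg_delta_min <= mean_delta_min <= 1"
            )
        if self.window_cpgs < 2:
            raise ValueError("window_cpgs must be >= 2")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")

    @classmethod
    def disease(cls, **kw) -> "DmrParams":
        """Relaxed mode for disease comparisons (mean delta >= 20%)."""
        kw.setdefault("mean_delta_min", 0.20)
        return cls(**kw)


@dataclass(frozen=True)
class SeedWindow:
    """A qualifying sliding window of ``window_cpgs`` consecutive CpGs."""

    chrom: str
    start_index: int            # index into the chromosome's common-CpG array
    positions: tuple[int, ...]
    mean_delta: float


def _blocks(pos: np.ndarray, delta: np.ndarray,
            params: DmrParams) -> list[tuple[int, int]]:
    """Maximal index runs where every CpG passes the per-CpG magnitude
    threshold, all deltas share one sign, and adjacent gaps fit.

    These three criteria are hereditary (true for a run iff true for every
    sub-run), so every candidate DMR lies inside exactly one block.
    """
    n = len(pos)
    ok = np.abs(delta) >= params.per_cpg_delta_min
    blocks = []
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and ok[j + 1]
               and np.sign(delta[j + 1]) == np.sign(delta[i])
               and pos[j + 1] - pos[j] <= params.max_gap_bp):
            j += 1
        blocks.append((i, j))
        i = j + 1
    return blocks


def _seed_starts(csum: np.ndarray, lo: int, hi: int,
                 params: DmrParams) -> np.ndarray:
    """Start indices (absolute) of qualifying seed windows inside block
    [lo, hi] (inclusive), given a chromosome-wide cumulative delta sum."""
    w = params.window_cpgs
    if hi - lo + 1 < w:
        return np.empty(0, dtype=np.int64)
    starts = np.arange(lo, hi - w + 2)
    means = (csum[starts + w] - csum[starts]) / w
    return starts[np.abs(means) >= params.mean_delta_min - MEAN_TOL]


def find_seed_windows(paired: PairedTrack,
                      params: DmrParams = DmrParams()) -> list[SeedWindow]:
    """Scan every window of ``window_cpgs`` consecutive common CpGs (step of
    one CpG) for seeds: one sign, every |delta| past the per-CpG minimum,
    |mean delta| past the region threshold, all gaps within the bp limit."""
    seeds: list[SeedWindow] = []
    w = params.window_cpgs
    for chrom, pos, delta in paired.per_chrom():
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        for lo, hi in _blocks(pos, delta, params):
            for s in _seed_starts(csum, lo, hi, params):
                mean = (csum[s + w] - csum[s]) / w
                seeds.append(SeedWindow(
                    chrom=chrom, start_index=int(s),
                    positions=tuple(int(p) for p in pos[s:s + w]),
                    mean_delta=float(mean),
                ))
    return seeds


def _maximal_runs(lo: int, hi: int, csum: np.ndarray, seed_starts: np.ndarray,
                  params: DmrParams) -> list[tuple[int, int]]:
    """All maximal qualifying runs inside a block.

    A run [i, j] qualifies iff it is at least window_cpgs long, its
    |mean delta| passes mean_delta_min and it contains a seed window.  For
    each i the largest qualifying j is found; runs contained in an earlier
    (longer-reaching) run are discarded.
    """
    w = params.window_cpgs
    if len(seed_starts) == 0:
        return []
    seed_presence = np.zeros(hi - lo + 2, dtype=np.int64)
    seed_presence[seed_starts - lo] = 1
    seed_cum = np.concatenate([[0], np.cumsum(seed_presence)])

    def has_seed(i: int, j: int) -> bool:
        # a seed starting in [i, j-w+1] lies fully inside [i, j]
        a, b = i - lo, j - w + 1 - lo
        return b >= a and seed_cum[b + 1] - seed_cum[a] > 0

    runs: list[tuple[int, int]] = []
    best_j = -1
    for i in range(lo, hi - w + 2):
        found = -1
        for j in range(hi, i + w - 2, -1):
            mean = (csum[j + 1] - csum[i]) / (j - i + 1)
            if abs(mean) >= params.mean_delta_min - MEAN_TOL and has_seed(i, j):
                found = j
                break
        if found > best_j:
            runs.append((i, found))
            best_j = found
    return runs


def _run_qualifies(i: int, j: int, csum: np.ndarray, seed_starts: np.ndarray,
                   params: DmrParams) -> bool:
    w = params.window_cpgs
    if j - i + 1 < w:
        return False
    mean = (csum[j + 1] - csum[i]) / (j - i + 1)
    if abs(mean) < params.mean_delta_min - MEAN_TOL:
        return False
    return bool(np.any((seed_starts >= i) & (seed_starts <= j - w + 1)))


def _resolve_overlaps(runs: list[tuple[int, int]], csum: np.ndarray,
                      seed_starts: np.ndarray,
                      params: DmrParams) -> list[tuple[int, int]]:
    """Make runs disjoint: overlapping runs merge iff the union qualifies,
    otherwise the run with more CpGs wins (ties to the smaller start)."""
    if not runs:
        return []
    runs = sorted(runs)
    out = [runs[0]]
    for r in runs[1:]:
        cur = out[-1]
        if r[0] <= cur[1]:  # share at least one CpG
            union = (cur[0], max(cur[1], r[1]))
            if _run_qualifies(*union, csum, seed_starts, params):
                out[-1] = union
            else:
                len_cur = cur[1] - cur[0] + 1
                len_r = r[1] - r[0] + 1
                if len_r > len_cur:
                    out[-1] = r
        else:
            out.append(r)
    return out


def extend_and_merge(seeds: Sequence[SeedWindow], paired: PairedTrack,
                     params: DmrParams = DmrParams()) -> list[Dmr]:
    """Extend seed windows until the cutoff criteria fail and merge.

    Each reported DMR is the maximal run of consecutive common CpGs that
    satisfies all per-CpG, gap and region-mean criteria and contains at
    least one seed; overlapping runs are resolved as documented in the
    module docstring.  Output is disjoint and coordinate-sorted.
    """
    seeds_by_chrom: dict[str, list[int]] = {}
    for s in seeds:
        seeds_by_chrom.setdefault(s.chrom, []).append(s.start_index)
    dmrs: list[Dmr] = []
    for chrom, pos, delta in paired.per_chrom():
        chrom_seeds = np.asarray(sorted(seeds_by_chrom.get(chrom, [])),
                                 dtype=np.int64)
        if not len(chrom_seeds):
            continue
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        runs: list[tuple[int, int]] = []
        for lo, hi in _blocks(pos, delta, params):
            in_block = chrom_seeds[(chrom_seeds >= lo) & (chrom_seeds <= hi)]
            block_runs = _maximal_runs(lo, hi, csum, in_block, params)
            runs.extend(_resolve_overlaps(block_runs, csum, in_block, params))
        for i, j in runs:
            mean = (csum[j + 1] - csum[i]) / (j - i + 1)
            dmrs.append(make_dmr(chrom, pos[i:j + 1], mean))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return [replace(d, name=f"dmr_{k + 1}") for k, d in enumerate(dmrs)]


def call_dmrs_paired(paired: PairedTrack,
                     params: DmrParams = DmrParams()) -> list[Dmr]:
    """Seed-and-extend on an already intersected/smoothed paired track."""
    return extend_and_merge(find_seed_windows(paired, params), paired, params)


def call_dmrs(a: MethylomeTrack, b: MethylomeTrack,
              params: DmrParams = DmrParams(),
              smooth_window: int = 3,
              smooth_order: str = SMOOTH_AFTER_INTERSECT) -> list[Dmr]:
    """Full caller: intersect the two preprocessed tracks, smooth, scan seed
    windows and extend/merge.  Deterministic."""
    paired = intersect_tracks(a, b, smooth_window=smooth_window,
                              smooth_order=smooth_order)
    if not len(paired):
        log.warning("call_dmrs: empty track intersection, no DMRs")
        return []
    return call_dmrs_paired(paired, params)


def dmr_cpg_cover(dmrs: Sequence[Dmr]) -> set[tuple[str, int]]:
    """Set of (chrom, pos) CpG sites covered by a DMR list."""
    return {(d.chrom, p) for d in dmrs for p in d.cpg_positions}


def mean_dmr_size_bp(dmrs: Sequence[Dmr]) -> float:
    if not dmrs:
        return float("nan")
    return float(np.mean([d.length for d in dmrs]))
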