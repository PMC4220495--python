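"""Naive reference implementations used to validate the optimized caller.

Everything here recomputes results by exhaustive enumeration with no shared
code path with :mod:`methwave.dmr`: every contiguous CpG run is generated
and every criterion re-checked from the raw deltas.  Intended for small
inputs (tens of CpGs per chromosome) in tests and validation scripts.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .dmr import MEAN_TOL, DmrParams
from .types import Dmr, PairedTrack, make_dmr


def _criteria_hold(pos: Sequence[int], delta: Sequence[float],
                   params: DmrParams) -> bool:
    """Hereditary criteria for an arbitrary CpG run: one sign, per-CpG
    magnitude, adjacent gaps."""
    d = np.asarray(delta, dtype=float)
    if (np.abs(d) < params.per_cpg_delta_min).any():
        return False
    if not ((d > 0).all() or (d < 0).all()):
        return False
    gaps = np.diff(np.asarray(pos))
    return not (gaps > params.max_gap_bp).any()


def _is_seed(pos, delta, params: DmrParams) -> bool:
    if len(pos) != params.window_cpgs:
        return False
    if not _criteria_hold(pos, delta, params):
        return False
    return abs(float(np.mean(delta))) >= params.mean_delta_min - MEAN_TOL


def _qualifies(pos, delta, params: DmrParams) -> bool:
    """Full region criteria including seed-window containment."""
    n = len(pos)
    w = params.window_cpgs
    if n < w:
        return False
    if not _criteria_hold(pos, delta, params):
        return False
    if abs(float(np.mean(delta))) < params.mean_delta_min - MEAN_TOL:
        return False
    return any(
        _is_seed(pos[s:s + w], delta[s:s + w], params)
        for s in range(n - w + 1)
    )


def brute_force_dmrs(paired: PairedTrack,
                     params: DmrParams = DmrParams()) -> list[Dmr]:
    """Enumerate every contiguous run of common CpGs, keep qualifying runs
    not strictly contained in another qualifying run, then resolve overlaps
    by the documented rule (merge iff the union qualifies, else more CpGs
    win, ties to the smaller start)."""
    out: list[Dmr] = []
    for chrom, pos, delta in paired.per_chrom():
        n = len(pos)
        qual = [
            (i, j)
            for i in range(n)
            for j in range(i, n)
            if _qualifies(pos[i:j + 1], delta[i:j + 1], params)
        ]
        maximal = [
            (i, j) for (i, j) in qual
            if not any((a <= i and j <= b and (a, b) != (i, j))
                       for (a, b) in qual)
        ]
        maximal.sort()
        kept: list[tuple[int, int]] = []
        for r in maximal:
            if kept and r[0] <= kept[-1][1]:
                cur = kept[-1]
                union = (cur[0], max(cur[1], r[1]))
                if _qualifies(pos[union[0]:union[1] + 1],
                              delta[union[0]:union[1] + 1], params):
                    kept[-1] = union
                elif (r[1] - r[0]) > (cur[1] - cur[0]):
                    kept[-1] = r
            else:
                kept.append(r)
        for i, j in kept:
            out.append(make_dmr(chrom, pos[i:j + 1],
                                float(np.mean(delta[i:j + 1]))))
    out.sort(key=lambda d: (d.chrom, d.start))
    return out
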