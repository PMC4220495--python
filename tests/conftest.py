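import numpy as np
import pandas as pd
import pytest

from methwave.types import PairedTrack, MethylomeTrack


def paired_from(pos, delta, chrom="chr1"):
    """Build a PairedTrack directly from positions and smoothed deltas."""
    pos = np.asarray(pos)
    delta = np.asarray(delta, dtype=float)
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "level_a": 0.5 + delta / 2, "level_b": 0.5 - delta / 2,
    })
    df["smoothed_a"] = df["level_a"]
    df["smoothed_b"] = df["level_b"]
    df["delta"] = delta
    return PairedTrack(df)


def track_from(pos, level, coverage=10, chrom="chr1"):
    pos = np.asarray(pos)
    return MethylomeTrack(pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "level": np.asarray(level, dtype=float),
        "coverage": np.broadcast_to(coverage, pos.shape).copy(),
    }))


def random_paired(rng, n_max=50, span=5000, chrom="chr1"):
    """Random small paired track for oracle comparisons."""
    n = int(rng.integers(5, n_max + 1))
    pos = np.sort(rng.choice(np.arange(0, span, 2), size=n, replace=False))
    delta = np.round(rng.uniform(-0.7, 0.7, size=n), 3)
    return paired_from(pos, delta, chrom=chrom)


def dmr_key(dmrs, decimals=9):
    return [(d.chrom, d.start, d.end, d.n_cpgs, round(d.mean_delta, decimals),
             d.direction) for d in dmrs]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
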