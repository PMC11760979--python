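import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_intervals(rng, n, contig="chr1", contig_len=10_000, max_len=300):
    """Random (possibly overlapping) valid intervals on a toy contig."""
    from chromdyn import GenomicInterval

    starts = rng.integers(0, contig_len - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return [
        GenomicInterval(contig, int(s), int(s + l))
        for s, l in zip(starts, lengths)
    ]


def random_track(rng, contig="chr1", contig_len=10_000, n_segments=20):
    """Random non-overlapping piecewise-constant track on a toy contig."""
    from chromdyn import SignalTrack

    points = np.sort(rng.choice(contig_len, size=2 * n_segments, replace=False))
    segments = []
    for i in range(0, len(points) - 1, 2):
        value = float(rng.uniform(0, 5))
        segments.append((contig, int(points[i]), int(points[i + 1]), value))
    return SignalTrack.from_segments(segments)


def dense_union(intervals, contig_len=10_000):
    """Brute-force per-base covered-base boolean array (single contig)."""
    covered = np.zeros(contig_len, dtype=bool)
    for iv in intervals:
        covered[iv.start : iv.end] = True
    return covered


def runs_of(covered):
    """(start, end) runs of True in a boolean array — an independent merge."""
    padded = np.concatenate([[False], covered, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
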