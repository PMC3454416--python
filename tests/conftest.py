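import numpy as np
import pytest

from bivenrich import GenomeAssembly, Interval, IntervalTrack, PointSet, merge_track


@pytest.fixture
def toy_genome():
    """Single 1 kb chromosome, the scale at which results are hand-checkable."""
    return GenomeAssembly("toy", {"c1": 1000})


@pytest.fixture
def toy_track():
    return merge_track(IntervalTrack([Interval("c1", 100, 200)]))


def random_instance(rng, n_points=100, n_intervals=50, chrom_len=10_000, n_chroms=3):
    """A random small track + point set for oracle comparisons."""
    chroms = [f"c{i}" for i in range(1, n_chroms + 1)]
    intervals = []
    for _ in range(int(rng.integers(1, n_intervals + 1))):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, chrom_len + 1))
        intervals.append(Interval(chrom, start, end))
    track = merge_track(IntervalTrack(intervals))
    pts = set()
    for _ in range(int(rng.integers(1, n_points + 1))):
        pts.add((chroms[int(rng.integers(0, n_chroms))], int(rng.integers(0, chrom_len))))
    return PointSet(sorted(pts)), track


def brute_force_points_in_track(points, track):
    """Independent per-point, per-interval scan (the oracle)."""
    count = 0
    for chrom, pos in points.points:
        for iv in track.intervals:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                count += 1
                break
    return count
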