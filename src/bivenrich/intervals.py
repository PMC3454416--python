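"""Genomic interval tracks and point sets: merging, overlap counting, coverage,
the enrichment ratio, and length/gap-preserving track randomization.

All coordinates are 0-based, half-open. An array probe is a single point,
the first base pair of its probe sequence, i.e. the 1-bp interval
``[pos, pos + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .genome import GenomeAssembly, GenomeError


class TrackError(ValueError):
    """Contract violation on an interval track (bounds, merge state, layout)."""


class BedParseError(ValueError):
    """Malformed BED or point file; message carries the line number."""


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:  # type: ignore[override]
        return 3

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalTrack:
    """A set of genomic segments, optionally reduced to a disjoint sorted union.

    ``merged`` is True only when, per chromosome, intervals are sorted,
    pairwise disjoint and non-adjacent (``prev.end < next.start``). Overlap
    counting, coverage and randomization require a merged track so no base
    pair is counted twice.
    """

    intervals: list[Interval]
    merged: bool = False
    names: list[str] | None = None  # BED column 4, carried through I/O only

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        for iv in self.intervals:
            if iv.start < 0 or iv.start >= iv.end:
                raise TrackError(f"invalid interval {iv}: need 0 <= start < end")
        if self.names is not None and len(self.names) != len(self.intervals):
            raise TrackError("names and intervals length mismatch")

    def __len__(self) -> int:
        return len(self.intervals)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start; cached."""
        if self._index is None:
            index: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                index.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._index = {}
            for chrom, pairs in index.items():
                pairs.sort()
                arr = np.asarray(pairs, dtype=np.int64)
                self._index[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
        return self._index

    def validate_bounds(self, genome: GenomeAssembly) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise GenomeError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length_of(iv.chrom):
                raise TrackError(f"interval {iv} exceeds chromosome length")


@dataclass
class PointSet:
    """A set of genomic points (chrom, 0-based position), optionally named.

    Duplicate positions are rejected unless ``allow_duplicates`` is set; the
    probe tracks this package analyzes have one point per probe.
    """

    points: list[tuple[str, int]]
    names: list[str] | None = None
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.names is not None and len(self.names) != len(self.points):
            raise TrackError("names and points length mismatch")
        if not self.allow_duplicates and len(set(self.points)) != len(self.points):
            raise TrackError("duplicate points (pass allow_duplicates=True to permit)")

    def __len__(self) -> int:
        return len(self.points)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome sorted position arrays."""
        index: dict[str, list[int]] = {}
        for chrom, pos in self.points:
            index.setdefault(chrom, []).append(pos)
        return {c: np.asarray(sorted(p), dtype=np.int64) for c, p in index.items()}

    def validate_bounds(self, genome: GenomeAssembly) -> None:
        for chrom, pos in self.points:
            if chrom not in genome:
                raise GenomeError(f"point on chromosome {chrom!r} absent from assembly")
            if not 0 <= pos < genome.length_of(chrom):
                raise TrackError(f"point ({chrom}, {pos}) outside chromosome bounds")

    def subset(self, indices: Sequence[int]) -> "PointSet":
        return PointSet(
            points=[self.points[i] for i in indices],
            names=[self.names[i] for i in indices] if self.names is not None else None,
            allow_duplicates=self.allow_duplicates,
        )


def merge_track(track: IntervalTrack) -> IntervalTrack:
    """Reduce a track to its union: sorted, disjoint, non-adjacent segments.

    Adjacent half-open intervals (prev.end == next.start) are coalesced, so
    the result covers exactly the same base pairs with the fewest segments.
    Names are dropped (a merged segment may span several named regions).
    """
    merged: list[Interval] = []
    for chrom, (starts, ends) in sorted(track.by_chrom().items()):
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, int(e))
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        merged.append(Interval(chrom, cur_s, cur_e))
    return IntervalTrack(intervals=merged, merged=True)


def extend_and_clamp(
    track: IntervalTrack, genome: GenomeAssembly, flank: int
) -> IntervalTrack:
    """Widen every interval by ``flank`` bp on both sides, clamped to the
    chromosome; the +/-2 kb promoter-context extension of gene coordinates.
    The result is not merged (extended regions may now overlap)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for iv in track.intervals:
        length = genome.length_of(iv.chrom)
        out.append(Interval(iv.chrom, max(0, iv.start - flank), min(length, iv.end + flank)))
    return IntervalTrack(intervals=out, merged=False, names=track.names)


def _require_merged(track: IntervalTrack) -> None:
    if not track.merged:
        raise TrackError("operation requires a merged track; call merge_track first")


def points_in_track(points: PointSet, track: IntervalTrack) -> int:
    """Number of points falling inside the track union.

    For point probes this equals the base-pair overlap between the probe
    track and the region track.
    """
    return int(in_track_mask(points, track).sum())


def in_track_mask(points: PointSet, track: IntervalTrack) -> np.ndarray:
    """Boolean membership per point, in the order of ``points.points``."""
    _require_merged(track)
    index = track.by_chrom()
    mask = np.zeros(len(points), dtype=bool)
    by_chrom_idx: dict[str, list[int]] = {}
    for i, (chrom, _) in enumerate(points.points):
        by_chrom_idx.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom_idx.items():
        if chrom not in index:
            continue
        starts, ends = index[chrom]
        pos = np.asarray([points.points[i][1] for i in idxs], dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        mask[np.asarray(idxs)] = ok
    return mask


def _count_sorted_positions(
    pos_by_chrom: dict[str, np.ndarray], index: dict[str, tuple[np.ndarray, np.ndarray]]
) -> int:
    """Fast overlap count used in the Monte Carlo loop: per chromosome, count
    sorted positions inside sorted disjoint segments via two searchsorted."""
    total = 0
    for chrom, pos in pos_by_chrom.items():
        if chrom not in index:
            continue
        starts, ends = index[chrom]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        total += int((hi - lo).sum())
    return total


def track_coverage_bp(track: IntervalTrack) -> int:
    """Total base pairs covered by a merged track."""
    _require_merged(track)
    return sum(iv.end - iv.start for iv in track.intervals)


def enrichment_ratio(
    points: PointSet, track: IntervalTrack, genome: GenomeAssembly
) -> float:
    """Ratio of the proportion of probe coordinates covered by the track to
    the proportion of non-probe coordinates covered by the track.

    With n probe points (1 bp each), k of them inside the track, C covered
    base pairs and genome size G:

        enrichment = (k / n) / ((C - k) / (G - n))

    The k in-track probe base pairs are excluded from the non-probe covered
    count and all n probe base pairs from the non-probe total.
    Returns 0 when k = 0, and +inf when the track is entirely probe bp.
    """
    _require_merged(track)
    n = len(points)
    if n == 0:
        raise ValueError("need at least one point")
    G = genome.total_length
    if G <= n:
        raise ValueError("genome smaller than the point set")
    k = points_in_track(points, track)
    if k == 0:
        return 0.0
    C = track_coverage_bp(track)
    if C - k == 0:
        return float("inf")
    return (k / n) / ((C - k) / (G - n))


def randomize_track(
    track: IntervalTrack,
    genome: GenomeAssembly,
    rng: np.random.Generator | int,
) -> IntervalTrack:
    """Draw one track from the null model that preserves, per chromosome, the
    multiset of segment lengths and the multiset of gaps *between* segments.

    Lengths and internal gaps are independently, uniformly permuted and laid
    out alternately; the leading offset is uniform on the remaining slack, so
    only between-segment distances are constrained, not the flanks to the
    chromosome ends. Segments never move across chromosomes.
    """
    _require_merged(track)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out: list[Interval] = []
    for chrom, (starts, ends) in sorted(track.by_chrom().items()):
        lengths = ends - starts
        gaps = starts[1:] - ends[:-1]
        chrom_len = genome.length_of(chrom)
        slack = chrom_len - int(lengths.sum()) - int(gaps.sum())
        if slack < 0:
            raise TrackError(
                f"randomization infeasible on {chrom}: segments + gaps exceed length"
            )
        lengths = rng.permutation(lengths)
        gaps = rng.permutation(gaps)
        cursor = int(rng.integers(0, slack + 1))
        for i, length in enumerate(lengths):
            out.append(Interval(chrom, cursor, cursor + int(length)))
            cursor += int(length)
            if i < len(gaps):
                cursor += int(gaps[i])
    return IntervalTrack(intervals=out, merged=True)


def read_bed(path: str | Path) -> IntervalTrack:
    """Read a BED3/BED4 file (tab-separated, 0-based half-open)."""
    path = Path(path)
    intervals: list[Interval] = []
    names: list[str] = []
    saw_name = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: need 0 <= start < end")
            intervals.append(Interval(chrom, start, end))
            if len(fields) >= 4:
                saw_name = True
                names.append(fields[3])
            else:
                names.append("")
    return IntervalTrack(intervals=intervals, names=names if saw_name else None)


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals):
            if track.names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_points_bed(points: PointSet, path: str | Path) -> None:
    """Export points as 1-bp BED4 intervals (probe ID in the name column)."""
    with open(path, "w") as fh:
        for i, (chrom, pos) in enumerate(points.points):
            name = points.names[i] if points.names is not None else f"pt{i}"
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\n")
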