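"""Map probe points to named gene regions and split points by track overlap.

Annotation uses the per-gene (unmerged) extended intervals so a point inside
two overlapping extended genes is credited to both; the enrichment
statistics elsewhere use the merged union so no base pair is double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .genome import GenomeAssembly
from .intervals import Interval, IntervalTrack, PointSet, extend_and_clamp, in_track_mask


@dataclass(frozen=True)
class GeneRegion:
    """A named gene interval (after any flank extension, before merging)."""

    gene_id: str
    interval: Interval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


def gene_regions_from_track(track: IntervalTrack) -> list[GeneRegion]:
    """Interpret a BED4 track as named gene regions."""
    if track.names is None:
        raise ValueError("gene track needs a name column (BED4)")
    return [
        GeneRegion(gene_id=name, interval=iv)
        for iv, name in zip(track.intervals, track.names)
    ]


def extend_gene_regions(
    genes: Sequence[GeneRegion], genome: GenomeAssembly, flank: int
) -> list[GeneRegion]:
    track = IntervalTrack(
        intervals=[g.interval for g in genes], names=[g.gene_id for g in genes]
    )
    extended = extend_and_clamp(track, genome, flank)
    return gene_regions_from_track(extended)


def annotate_points(
    points: PointSet, genes: Sequence[GeneRegion]
) -> list[set[str]]:
    """For each point, the set of gene IDs whose region contains it.

    Returned list is aligned with ``points.points``; a point hitting no gene
    maps to the empty set, a point inside overlapping regions to several IDs.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g.gene_id
        )
    out: list[set[str]] = []
    for chrom, pos in points.points:
        tree = trees.get(chrom)
        out.append({hit.data for hit in tree[pos]} if tree is not None else set())
    return out


def nonredundant_genes(annotations: Sequence[set[str]]) -> list[str]:
    """Deduplicated, sorted gene list across all annotated points."""
    return sorted(set().union(*annotations)) if annotations else []


def partition_by_overlap(
    points: PointSet, track: IntervalTrack
) -> tuple[PointSet, PointSet]:
    """Split points into (inside, outside) the merged track; disjoint and
    exhaustive, so |inside| + |outside| = |points|."""
    mask = in_track_mask(points, track)
    inside = points.subset([i for i, m in enumerate(mask) if m])
    outside = points.subset([i for i, m in enumerate(mask) if not m])
    return inside, outside


def write_gene_list(gene_ids: Sequence[str], path: str | Path) -> None:
    """One gene ID per line — the format ontology web tools ingest."""
    with open(path, "w") as fh:
        for gid in gene_ids:
            fh.write(f"{gid}\n")
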