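"""Synthetic study generator: genome, bivalent-like gene track, and a
probe-association table with planted enrichment structure.

The generator emulates the inputs of a promoter-array methylation-aging
study: ~27,578 point probes with per-age-group (slope, P) association
statistics, and ~1,792 gene regions that, after a +/-2 kb extension, cover a
small fraction c of an hg18-scale genome. Significant hyper-methylated
probes of each age group are planted inside the merged gene track with
probability q = min(1, rho * c), and uniformly outside otherwise, so the
expected measured enrichment ratio of that subset is ~ rho (exactly rho up
to an O(c) finite-genome correction). Hypo-methylated significant probes
and non-significant probes are uniform over the genome.

Defaults mirror the study scale: per-group (hyper, hypo) significant counts
(fetal 20/83, child 287/154, adult 1867/440), rho = 3, Bonferroni threshold
alpha / n_probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotate import GeneRegion, extend_gene_regions
from .genome import GenomeAssembly, write_chrom_sizes
from .intervals import (
    Interval,
    IntervalTrack,
    merge_track,
    track_coverage_bp,
    write_bed,
)
from .probes import AGE_GROUPS, ProbeSite, bonferroni_threshold, write_probe_table


class SyntheticConfigError(ValueError):
    """Infeasible generator configuration (packing or probe capacity)."""


# (hyper, hypo) significant probes per age group at the 27,578-probe scale
STUDY_SCALE_N_SIG: dict[str, tuple[int, int]] = {
    "fetal": (20, 83),
    "child": (287, 154),
    "adult": (1867, 440),
}
STUDY_SCALE_N_PROBES = 27_578


def scaled_n_sig(n_probes: int) -> dict[str, tuple[int, int]]:
    """Study-scale significant counts scaled to a smaller/larger array."""
    f = n_probes / STUDY_SCALE_N_PROBES
    return {
        g: (max(1, round(nh * f)), max(1, round(nl * f)))
        for g, (nh, nl) in STUDY_SCALE_N_SIG.items()
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the study-scale conditions."""

    n_chroms: int = 22
    chrom_length: int = 140_000_000
    n_genes: int = 1792
    gene_length_median: float = 20_000.0  # bp, log-normal median
    gene_length_sigma: float = 0.6  # log-scale dispersion
    flank: int = 2000
    n_probes: int = 27_578
    n_sig: dict[str, tuple[int, int]] | None = None  # defaults to scaled_n_sig(n_probes)
    target_enrichment: float = 3.0  # planted rho
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise SyntheticConfigError("need at least one chromosome of positive length")
        if self.target_enrichment < 0:
            raise SyntheticConfigError("target_enrichment must be >= 0")
        if self.n_sig is None:
            self.n_sig = scaled_n_sig(self.n_probes)
        for group, (nh, nl) in self.n_sig.items():
            if group not in AGE_GROUPS:
                raise SyntheticConfigError(f"unknown age group {group!r}")
            if nh < 0 or nl < 0:
                raise SyntheticConfigError("significant counts must be >= 0")
        total_sig = sum(nh + nl for nh, nl in self.n_sig.values())
        if total_sig > self.n_probes:
            raise SyntheticConfigError("more significant probes than probes")

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.n_probes, self.alpha)


def generate_genome(config: SyntheticConfig) -> GenomeAssembly:
    """Equal-length chromosomes chr1..chrN (deterministic)."""
    return GenomeAssembly(
        name="synthetic",
        chrom_lengths={f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)},
    )


def generate_gene_track(
    config: SyntheticConfig, genome: GenomeAssembly, rng: np.random.Generator | None = None
) -> list[GeneRegion]:
    """Place n_genes non-overlapping regions with log-normal lengths.

    Each gene lands on a uniformly chosen chromosome; per chromosome the
    non-overlapping layout is drawn uniformly (uniform cut positions in the
    free space). Extension by the flank happens downstream and may create
    overlaps, which merging resolves.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = list(genome.chrom_lengths)
    mu = math.log(config.gene_length_median)
    lengths = np.maximum(
        1, rng.lognormal(mu, config.gene_length_sigma, size=config.n_genes).astype(np.int64)
    )
    assignment = rng.integers(0, len(chroms), size=config.n_genes)
    genes: list[GeneRegion] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(assignment == ci)
        if idx.size == 0:
            continue
        chrom_lens = lengths[idx]
        free = genome.length_of(chrom) - int(chrom_lens.sum())
        if free < 0:
            raise SyntheticConfigError(
                f"cannot pack {idx.size} genes ({int(chrom_lens.sum())} bp) on {chrom}"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=idx.size))
        offsets = cuts + np.concatenate([[0], np.cumsum(chrom_lens[:-1])])
        for start, length in zip(offsets, chrom_lens):
            gid += 1
            genes.append(
                GeneRegion(f"G{gid:05d}", Interval(chrom, int(start), int(start + length)))
            )
    return genes


def _cumlen_sampler(intervals: list[Interval]) -> tuple[np.ndarray, np.ndarray, list[Interval]]:
    lens = np.asarray([iv.end - iv.start for iv in intervals], dtype=np.int64)
    return np.concatenate([[0], np.cumsum(lens)]), lens, intervals


def _sample_positions(
    intervals: list[Interval], n: int, rng: np.random.Generator, used: set[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Sample n distinct unused positions uniformly over the given segments."""
    cum, _, ivs = _cumlen_sampler(intervals)
    total = int(cum[-1])
    if total < n:
        raise SyntheticConfigError("not enough distinct base pairs to place probes")
    out: list[tuple[str, int]] = []
    while len(out) < n:
        r = int(rng.integers(0, total))
        j = int(np.searchsorted(cum, r, side="right")) - 1
        iv = ivs[j]
        pt = (iv.chrom, iv.start + (r - int(cum[j])))
        if pt not in used:
            used.add(pt)
            out.append(pt)
    return out


def _complement(track: IntervalTrack, genome: GenomeAssembly) -> list[Interval]:
    """Genome minus a merged track, as intervals."""
    index = track.by_chrom()
    out: list[Interval] = []
    for chrom, length in genome.chrom_lengths.items():
        if chrom not in index:
            out.append(Interval(chrom, 0, length))
            continue
        starts, ends = index[chrom]
        cursor = 0
        for s, e in zip(starts, ends):
            if s > cursor:
                out.append(Interval(chrom, cursor, int(s)))
            cursor = int(e)
        if cursor < length:
            out.append(Interval(chrom, cursor, length))
    return out


def generate_probe_table(
    config: SyntheticConfig,
    genome: GenomeAssembly,
    genes: list[GeneRegion],
    rng: np.random.Generator | None = None,
) -> list[ProbeSite]:
    """Generate the probe-association table with the planted signal.

    Each configured significant probe is significant in exactly its focal
    group (signal P ~ U(0, threshold); elsewhere P ~ U(threshold, 1));
    slopes are signed by direction with |slope| log-normal around a
    per-year methylation change of ~0.005.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    extended = extend_gene_regions(genes, genome, config.flank)
    merged = merge_track(
        IntervalTrack([g.interval for g in extended])
    ) if extended else IntervalTrack([], merged=True)
    C = track_coverage_bp(merged)
    G = genome.total_length
    c = C / G
    q = min(1.0, config.target_enrichment * c)
    thr = config.threshold

    n_hyper_total = sum(nh for nh, _ in config.n_sig.values())
    if q * n_hyper_total > C and C > 0:
        raise SyntheticConfigError("planted in-track probes exceed track capacity")

    whole = [Interval(ch, 0, ln) for ch, ln in genome.chrom_lengths.items()]
    outside = _complement(merged, genome) if len(merged) else whole

    used: set[tuple[str, int]] = set()
    probes: list[ProbeSite] = []
    pid = 0

    def _stats(focal: str | None, direction: int) -> dict[str, tuple[float, float]]:
        stats = {}
        for g in AGE_GROUPS:
            mag = float(rng.lognormal(math.log(0.005), 0.5))
            if g == focal:
                sign = direction
                p = float(rng.uniform(0.0, thr))
            else:
                sign = 1 if rng.integers(0, 2) else -1
                p = float(rng.uniform(thr, 1.0))
            stats[g] = (sign * mag, p)
        return stats

    def _new_probe(pt: tuple[str, int], focal: str | None, direction: int) -> None:
        nonlocal pid
        pid += 1
        probes.append(
            ProbeSite(f"cg{pid:08d}", pt[0], pt[1], _stats(focal, direction))
        )

    for group in AGE_GROUPS:
        nh, nl = config.n_sig.get(group, (0, 0))
        # hyper-significant: inside the track with probability q
        n_in = int(rng.binomial(nh, q)) if nh else 0
        if n_in and C == 0:
            n_in = 0
        for pt in _sample_positions(merged.intervals, n_in, rng, used):
            _new_probe(pt, group, +1)
        for pt in _sample_positions(outside, nh - n_in, rng, used):
            _new_probe(pt, group, +1)
        # hypo-significant: uniform over the genome
        for pt in _sample_positions(whole, nl, rng, used):
            _new_probe(pt, group, -1)

    n_rest = config.n_probes - len(probes)
    for pt in _sample_positions(whole, n_rest, rng, used):
        _new_probe(pt, None, 0)
    return probes


def generate_study(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> dict[str, object]:
    """Generate a complete, seeded study; optionally write its three files.

    Returns the in-memory objects and, when ``outdir`` is given, the paths
    of ``genome.chrom.sizes``, ``genes.bed`` (BED4, unextended coordinates)
    and ``probes.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config)
    genes = generate_gene_track(config, genome, rng)
    probes = generate_probe_table(config, genome, genes, rng)
    result: dict[str, object] = {"genome": genome, "genes": genes, "probes": probes}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome_path = outdir / "genome.chrom.sizes"
        genes_path = outdir / "genes.bed"
        probes_path = outdir / "probes.tsv"
        write_chrom_sizes(genome, genome_path)
        write_bed(
            IntervalTrack(
                [g.interval for g in genes], names=[g.gene_id for g in genes]
            ),
            genes_path,
        )
        write_probe_table(probes, probes_path)
        result["paths"] = {
            "genome": genome_path,
            "genes": genes_path,
            "probes": probes_path,
        }
    return result
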