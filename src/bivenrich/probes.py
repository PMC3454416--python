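"""Probe-association tables and the probe subsets analyzed per age group.

A probe-association table carries, for each array CpG probe, its genomic
point and a (slope, P-value) pair per age group from the upstream
methylation-vs-age regressions. This module derives the subsets fed to the
enrichment tests: Bonferroni-significant sites per group, sites unique to a
group, hyper-/hypo-methylated splits (by slope sign), and top-k sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import PointSet

AGE_GROUPS = ("fetal", "child", "adult")


class ProbeTableError(ValueError):
    """Malformed probe table or inconsistent probe/point mapping."""


@dataclass(frozen=True)
class ProbeSite:
    """One array CpG probe: a genomic point plus per-group association stats.

    ``stats`` maps age group -> (slope, p_value). The slope is the
    methylation change per year from the age regression; its sign defines
    hyper- (>0) vs hypo- (<0) methylation with age.
    """

    probe_id: str
    chrom: str
    position: int
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, (_, p) in self.stats.items():
            if not 0.0 <= p <= 1.0:
                raise ProbeTableError(
                    f"probe {self.probe_id}: p-value {p} for {group!r} outside [0, 1]"
                )


@dataclass
class SitePartition:
    """All derived probe subsets for one age group at one threshold."""

    group: str
    threshold: float
    significant: PointSet
    unique: PointSet
    hyper: PointSet
    hypo: PointSet
    top_k: PointSet
    n_zero_slope: int = 0


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise Bonferroni cutoff alpha / n_tests.

    For the 27,578-probe array at alpha = 0.05 this is 1.81304e-06.
    """
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / n_tests


def _points(probes: Sequence[ProbeSite]) -> PointSet:
    return PointSet(
        points=[(p.chrom, p.position) for p in probes],
        names=[p.probe_id for p in probes],
    )


def _check_group(probes: Sequence[ProbeSite], group: str) -> None:
    for p in probes:
        if group not in p.stats:
            raise ProbeTableError(f"probe {p.probe_id} has no stats for group {group!r}")


def significant_sites(
    probes: Sequence[ProbeSite], group: str, threshold: float
) -> PointSet:
    """Probes with p strictly below the threshold in the given group."""
    _check_group(probes, group)
    return _points([p for p in probes if p.stats[group][1] < threshold])


def unique_sites(probes: Sequence[ProbeSite], group: str, threshold: float) -> PointSet:
    """Probes significant in the focal group and in no other group.

    "Not significant" in another group means p >= threshold there, keeping
    the two regimes exhaustive at the boundary.
    """
    _check_group(probes, group)
    others = [g for g in AGE_GROUPS if g != group]
    for g in others:
        _check_group(probes, g)
    keep = [
        p
        for p in probes
        if p.stats[group][1] < threshold
        and all(p.stats[g][1] >= threshold for g in others)
    ]
    return _points(keep)


def _probe_lookup(probes: Sequence[ProbeSite]) -> dict[tuple[str, int], ProbeSite]:
    return {(p.chrom, p.position): p for p in probes}


def split_hyper_hypo(
    probes: Sequence[ProbeSite], point_set: PointSet, group: str
) -> tuple[PointSet, PointSet]:
    """Split a point set into hyper- (slope > 0) and hypo- (slope < 0) sets.

    A slope of exactly 0 falls in neither set (both definitions are strict);
    such sites are counted by the caller via the returned set sizes.
    """
    lookup = _probe_lookup(probes)
    hyper_idx, hypo_idx = [], []
    for i, pt in enumerate(point_set.points):
        probe = lookup.get(pt)
        if probe is None or group not in probe.stats:
            raise ProbeTableError(f"point {pt} has no probe with stats for {group!r}")
        slope = probe.stats[group][0]
        if slope > 0:
            hyper_idx.append(i)
        elif slope < 0:
            hypo_idx.append(i)
    return point_set.subset(hyper_idx), point_set.subset(hypo_idx)


def top_k_sites(
    probes: Sequence[ProbeSite], point_set: PointSet, group: str, k: int
) -> PointSet:
    """The k most significant points of the set, by ascending p-value.

    Ties are broken by |slope| descending, then probe_id ascending, so the
    selection is deterministic. If the set has at most k points it is
    returned whole.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lookup = _probe_lookup(probes)
    keyed = []
    for i, pt in enumerate(point_set.points):
        probe = lookup.get(pt)
        if probe is None or group not in probe.stats:
            raise ProbeTableError(f"point {pt} has no probe with stats for {group!r}")
        slope, p = probe.stats[group]
        keyed.append((p, -abs(slope), probe.probe_id, i))
    keyed.sort()
    return point_set.subset([i for *_, i in keyed[:k]])


def partition_sites(
    probes: Sequence[ProbeSite], group: str, threshold: float, k: int = 100
) -> SitePartition:
    """Derive the full subset family for one age group."""
    sig = significant_sites(probes, group, threshold)
    uniq = unique_sites(probes, group, threshold)
    hyper, hypo = split_hyper_hypo(probes, uniq, group)
    top = top_k_sites(probes, uniq, group, k) if len(uniq) else uniq
    return SitePartition(
        group=group,
        threshold=threshold,
        significant=sig,
        unique=uniq,
        hyper=hyper,
        hypo=hypo,
        top_k=top,
        n_zero_slope=len(uniq) - len(hyper) - len(hypo),
    )


def _group_columns(columns: Iterable[str]) -> list[str]:
    slopes = {c[len("slope_"):] for c in columns if c.startswith("slope_")}
    ps = {c[len("p_"):] for c in columns if c.startswith("p_")}
    groups = sorted(slopes & ps)
    if slopes != ps:
        raise ProbeTableError(
            f"unpaired slope/p columns for groups {sorted(slopes ^ ps)}"
        )
    return groups


def read_probe_table(path: str | Path) -> list[ProbeSite]:
    """Read a tab-separated probe-association table.

    Expected header: ``probe_id  chrom  position`` then a
    ``slope_<group>``/``p_<group>`` pair per age group. Duplicate probe IDs,
    missing columns and non-numeric stats are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"probe_id": str, "chrom": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ProbeTableError(f"{path}: cannot parse probe table: {exc}") from exc
    for col in ("probe_id", "chrom", "position"):
        if col not in df.columns:
            raise ProbeTableError(f"{path}: missing required column {col!r}")
    groups = _group_columns(df.columns)
    if not groups:
        raise ProbeTableError(f"{path}: no slope_<group>/p_<group> column pairs")
    dup = df["probe_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # +1 header, +1 1-based
        raise ProbeTableError(f"{path}:{line}: duplicate probe_id")
    stat_cols = [c for g in groups for c in (f"slope_{g}", f"p_{g}")] + ["position"]
    for col in stat_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise ProbeTableError(f"{path}:{line}: non-numeric value in {col!r}")
        df[col] = numeric
    probes = []
    for row in df.itertuples(index=False):
        stats = {
            g: (float(getattr(row, f"slope_{g}")), float(getattr(row, f"p_{g}")))
            for g in groups
        }
        probes.append(
            ProbeSite(
                probe_id=row.probe_id,
                chrom=row.chrom,
                position=int(row.position),
                stats=stats,
            )
        )
    return probes


def write_probe_table(probes: Sequence[ProbeSite], path: str | Path) -> None:
    """Write probes in the format read_probe_table accepts (lossless)."""
    groups = sorted({g for p in probes for g in p.stats})
    header = ["probe_id", "chrom", "position"] + [
        c for g in groups for c in (f"slope_{g}", f"p_{g}")
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in probes:
            row = [p.probe_id, p.chrom, str(p.position)]
            for g in groups:
                slope, pv = p.stats[g]
                row += [repr(float(slope)), repr(float(pv))]
            fh.write("\t".join(row) + "\n")
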