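"""End-to-end analysis: load inputs, derive probe subsets, run the Monte
Carlo enrichment and case-control permutation tests, and write the report
tables, gene lists and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import (
    annotate_points,
    extend_gene_regions,
    gene_regions_from_track,
    nonredundant_genes,
    partition_by_overlap,
    write_gene_list,
)
from .casecontrol import label_permutation_test
from .enrichment import mc_enrichment_test
from .genome import read_chrom_sizes
from .intervals import IntervalTrack, merge_track, read_bed, write_points_bed
from .probes import (
    AGE_GROUPS,
    bonferroni_threshold,
    partition_sites,
    read_probe_table,
    top_k_sites,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    probe_table: Path
    gene_bed: Path
    genome_file: Path
    outdir: Path
    alpha: float = 0.05
    flank: int = 2000
    k_top: int = 100
    n_mc: int = 50_000
    n_perm: int = 50_000
    seed: int = 0
    groups: tuple[str, ...] = AGE_GROUPS

    def __post_init__(self) -> None:
        self.probe_table = Path(self.probe_table)
        self.gene_bed = Path(self.gene_bed)
        self.genome_file = Path(self.genome_file)
        self.outdir = Path(self.outdir)
        for p in (self.probe_table, self.gene_bed, self.genome_file):
            if not p.exists():
                raise FileNotFoundError(p)
        for name in ("alpha", "flank", "k_top", "n_mc", "n_perm"):
            if getattr(self, name) <= 0 and name != "flank":
                raise ValueError(f"{name} must be positive")


def _subset_seed(seed: int, label: str) -> int:
    """Stable per-subset RNG seed derived from the run seed and row label."""
    digest = hashlib.blake2s(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def run_analysis(config: AnalysisConfig) -> dict[str, object]:
    """Run the full analysis; returns the report tables and output paths.

    Outputs in ``config.outdir``: ``global_enrichment.tsv`` (one row per
    probe subset: n, observed overlap, enrichment, P), ``case_control.tsv``
    (one row per hyper-vs-hypo pair: proportions, fold difference, P),
    per-subset inside/outside site BEDs and inside gene lists, and
    ``manifest.json`` recording seed, parameters and input checksums.
    Deterministic: same inputs and seed give byte-identical reports.
    """
    cfg = config
    cfg.outdir.mkdir(parents=True, exist_ok=True)

    genome = read_chrom_sizes(cfg.genome_file)
    gene_track = read_bed(cfg.gene_bed)
    genes = gene_regions_from_track(gene_track)
    probes = read_probe_table(cfg.probe_table)

    extended = extend_gene_regions(genes, genome, cfg.flank)
    merged = merge_track(IntervalTrack([g.interval for g in extended]))
    merged.validate_bounds(genome)

    threshold = bonferroni_threshold(len(probes), cfg.alpha)
    log.info("threshold alpha/n = %g (n = %d probes)", threshold, len(probes))

    partitions = {
        g: partition_sites(probes, g, threshold, k=cfg.k_top) for g in cfg.groups
    }
    zero_slopes = {g: partitions[g].n_zero_slope for g in cfg.groups}
    for g, nz in zero_slopes.items():
        if nz:
            log.info("%s: %d zero-slope sites excluded from hyper/hypo", g, nz)

    # -- global enrichment rows ------------------------------------------
    subsets: list[tuple[str, object]] = []
    for g in cfg.groups:
        part = partitions[g]
        subsets.append((f"all_{g}", part.significant))
        subsets.append((f"unique_{g}", part.unique))
    hyper_hypo_pairs: list[tuple[str, object, object]] = []
    for g in cfg.groups:
        part = partitions[g]
        if len(part.hyper) and len(part.hypo):
            subsets.append((f"unique_hyper_{g}", part.hyper))
            subsets.append((f"unique_hypo_{g}", part.hypo))
            hyper_hypo_pairs.append((f"unique_{g}", part.hyper, part.hypo))
            top_h = top_k_sites(probes, part.hyper, g, cfg.k_top)
            top_l = top_k_sites(probes, part.hypo, g, cfg.k_top)
            subsets.append((f"top{cfg.k_top}_hyper_{g}", top_h))
            subsets.append((f"top{cfg.k_top}_hypo_{g}", top_l))
            hyper_hypo_pairs.append((f"top{cfg.k_top}_{g}", top_h, top_l))

    global_rows = []
    for label, points in subsets:
        if len(points) == 0:
            log.info("skipping empty subset %s", label)
            continue
        res = mc_enrichment_test(
            points, merged, genome, n_mc=cfg.n_mc, seed=_subset_seed(cfg.seed, label)
        )
        global_rows.append(res.to_row(track_name=label))
    global_df = pd.DataFrame(global_rows)

    # -- case-control rows -----------------------------------------------
    cc_rows = []
    for label, case, control in hyper_hypo_pairs:
        res = label_permutation_test(
            case,
            control,
            merged,
            n_perm=cfg.n_perm,
            seed=_subset_seed(cfg.seed, f"cc:{label}"),
        )
        cc_rows.append(res.to_row(f"{label}_hyper", f"{label}_hypo"))
    cc_df = pd.DataFrame(cc_rows)

    # -- gene lists for hyper subsets ------------------------------------
    gene_dir = cfg.outdir / "gene_lists"
    site_dir = cfg.outdir / "sites"
    gene_dir.mkdir(exist_ok=True)
    site_dir.mkdir(exist_ok=True)
    annotation_counts = {}
    for g in cfg.groups:
        part = partitions[g]
        if len(part.hyper) == 0:
            continue
        inside, outside = partition_by_overlap(part.hyper, merged)
        write_points_bed(inside, site_dir / f"unique_hyper_{g}_inside.bed")
        write_points_bed(outside, site_dir / f"unique_hyper_{g}_outside.bed")
        ann = annotate_points(inside, extended)
        gene_ids = nonredundant_genes(ann)
        write_gene_list(gene_ids, gene_dir / f"unique_hyper_{g}_inside_genes.txt")
        annotation_counts[f"unique_hyper_{g}"] = {
            "sites_inside": len(inside),
            "sites_outside": len(outside),
            "gene_hits_raw": int(sum(len(a) for a in ann)),
            "genes_nonredundant": len(gene_ids),
        }

    # -- write reports ----------------------------------------------------
    global_path = cfg.outdir / "global_enrichment.tsv"
    cc_path = cfg.outdir / "case_control.tsv"
    _write_report(global_df, global_path, float_cols=("enrichment", "p_value"))
    _write_report(
        cc_df,
        cc_path,
        float_cols=("case_prop", "control_prop", "fold_difference", "p_value"),
    )

    manifest = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "flank": cfg.flank,
        "k_top": cfg.k_top,
        "n_mc": cfg.n_mc,
        "n_perm": cfg.n_perm,
        "threshold": threshold,
        "groups": list(cfg.groups),
        "n_probes": len(probes),
        "inputs": {
            "probe_table": {"path": str(cfg.probe_table), "sha256": _sha256(cfg.probe_table)},
            "gene_bed": {"path": str(cfg.gene_bed), "sha256": _sha256(cfg.gene_bed)},
            "genome_file": {"path": str(cfg.genome_file), "sha256": _sha256(cfg.genome_file)},
        },
        "subset_sizes": {label: len(pts) for label, pts in subsets},
        "zero_slope_sites": zero_slopes,
        "annotation": annotation_counts,
    }
    manifest_path = cfg.outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "global_enrichment": global_df,
        "case_control": cc_df,
        "manifest": manifest,
        "paths": {
            "global_enrichment": global_path,
            "case_control": cc_path,
            "manifest": manifest_path,
        },
    }


def _write_report(df: pd.DataFrame, path: Path, float_cols: tuple[str, ...]) -> None:
    out = df.copy()
    for col in float_cols:
        if col in out.columns:
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)
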