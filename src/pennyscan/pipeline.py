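"""End-to-end orchestration: filters -> stats -> scans -> calls -> reports.

`run_full` executes the stages in dependency order on one input bundle
(VCF + population map, optional FASTA/GFF3) and writes fixed-name TSV/BED
outputs plus a provenance manifest into the run directory. Every stage is a
pure function of (inputs, config, seed), so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pennyscan import __version__
from pennyscan.clr_scan import SweepModel, clr_outliers, group_clr_scan
from pennyscan.differentiation import composite_scan, group_fst_profile
from pennyscan.diversity_stats import compute_sfs, make_windows, window_diversity, write_sfs
from pennyscan.io_formats import (
    apply_hard_filters,
    cluster_filter,
    read_fasta,
    read_gff,
    read_popmap,
    read_vcf,
    select_pass,
    write_bed,
    write_tsv,
)
from pennyscan.ld_decay import decay_curve
from pennyscan.outlier_calling import (
    assign_genes,
    calls_table,
    intersect_evidence,
    joint_outliers,
    psg_list,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    popmap: str = ""
    gff: str | None = None
    fasta: str | None = None
    outdir: str = "pennyscan_run"
    window_size: int = 20_000
    window_step: int = 10_000
    joint_quantile: float = 0.97
    clr_quantile: float = 0.99
    focal_group: str = "HG"
    other_group: str = "LG"
    min_snps: int = 5
    qd_min: float = 4.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    gq_min: float = 20.0
    cluster_window_bp: int = 4
    cluster_size: int = 3
    r_rec: float = 1e-8
    clr_grid_step: int = 10_000
    clr_radius: int = 200_000
    ld_max_dist: int = 300_000
    ld_bins: int = 100
    ld_maf_min: float = 0.05
    ld_mode: str = "genotype"
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extras = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_full(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the result bundle as a dict of DataFrames."""
    for label, p in (("vcf", cfg.vcf), ("popmap", cfg.popmap)):
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{label} input not found: {p!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("read")
    popmap = read_popmap(cfg.popmap)
    matrix, records = read_vcf(cfg.vcf, popmap)

    stage("filter")
    filter_counts = apply_hard_filters(
        records, qd_min=cfg.qd_min, fs_max=cfg.fs_max, mq_min=cfg.mq_min, gq_min=cfg.gq_min
    )
    cluster_filter(records, window_bp=cfg.cluster_window_bp, cluster_size=cfg.cluster_size)
    matrix = select_pass(matrix, records)

    if cfg.fasta:
        chrom_lengths = {name: len(s) for name, s in read_fasta(cfg.fasta).items()}
    else:
        # inferred length rounded up to a step multiple so the scan grid
        # covers the trailing partial window
        chrom_lengths = {
            chrom: int(-(-int(sub["pos"].max()) // cfg.window_step) * cfg.window_step)
            for chrom, sub in matrix.sites.groupby("chrom", sort=False)
        }
    windows = make_windows(chrom_lengths, cfg.window_size, cfg.window_step)

    stage("stats")
    pops = list(dict.fromkeys(matrix.populations))
    stats = pd.concat(
        [window_diversity(matrix, p, windows) for p in pops]
        + [
            window_diversity(matrix, None, windows, group=g)
            for g in dict.fromkeys(matrix.groups)
        ],
        ignore_index=True,
    )
    write_tsv(outdir / "window_stats.tsv", stats)

    stage("scan")
    groups = {g: [p for p, grp in {pp: gg for pp, gg in zip(matrix.populations, matrix.groups)}.items() if grp == g] for g in dict.fromkeys(matrix.groups)}
    high_pops = sorted(set(matrix.populations[matrix.groups == cfg.focal_group]))
    low_pops = sorted(set(matrix.populations[matrix.groups == cfg.other_group]))
    composite = composite_scan(
        matrix, windows, high_pops, low_pops,
        high_group=cfg.focal_group, low_group=cfg.other_group, min_snps=cfg.min_snps,
    )
    write_tsv(outdir / "composite_scan.tsv", composite)
    fst_profile = group_fst_profile(matrix, windows, cfg.focal_group, cfg.other_group)
    write_tsv(outdir / "group_fst.tsv", fst_profile)

    stage("clr")
    model = SweepModel(
        r_rec=cfg.r_rec, grid_step=cfg.clr_grid_step, radius=cfg.clr_radius
    )
    chrom = matrix.sites["chrom"].iloc[0] if matrix.n_sites else next(iter(chrom_lengths))
    points, phi, n_hap = group_clr_scan(
        matrix, cfg.focal_group, model, chrom_length=chrom_lengths[chrom]
    )
    write_tsv(outdir / "clr_points.tsv", points)
    clr_cut, clr_regions = clr_outliers(points, cfg.clr_quantile, cfg.clr_grid_step)
    write_bed(
        outdir / "clr_regions.bed",
        [
            (chrom, int(r.bed_start), int(r.bed_end), f"{r.max_clr:.3f}")
            for r in clr_regions.itertuples()
        ],
    )

    stage("call")
    joint = joint_outliers(composite, group=cfg.focal_group, q=cfg.joint_quantile)
    calls = intersect_evidence(joint, clr_regions, group=cfg.focal_group)
    genes = read_gff(cfg.gff) if cfg.gff else []
    if genes:
        calls = assign_genes(calls, genes)
    psgs = psg_list(calls)
    tbl = calls_table(calls)
    write_tsv(outdir / "selection_calls.tsv", tbl)
    (outdir / "psg_list.tsv").write_text("gene_id\n" + "".join(g + "\n" for g in psgs))

    stage("ld")
    ld = {}
    for g in dict.fromkeys(matrix.groups):
        mode = cfg.ld_mode
        if mode == "haplotype" and matrix.haplotypes is None:
            mode = "genotype"
        curve = decay_curve(
            matrix, group=g, max_dist=cfg.ld_max_dist, n_bins=cfg.ld_bins,
            maf_min=cfg.ld_maf_min, mode=mode,
        )
        write_tsv(outdir / f"ld_decay_{g}.tsv", curve)
        ld[g] = curve

    stage("sfs")
    try:
        sfs = compute_sfs(matrix, group=cfg.focal_group, folded=False, maf_min=0.0)
        write_sfs(outdir / f"sfs_{cfg.focal_group}.tsv", sfs)
    except ValueError:
        sfs = None

    manifest = {
        "pennyscan_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "n_sites_pass": int(matrix.n_sites),
        "filter_counts": filter_counts,
        "n_windows": len(windows),
        "clr_cutoff": float(clr_cut),
        "n_calls": len(calls),
        "n_psgs": len(psgs),
        "clr_haploid_n": int(n_hap),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "matrix": matrix,
        "stats": stats,
        "composite": composite,
        "joint": joint,
        "clr_points": points,
        "clr_regions": clr_regions,
        "clr_cutoff": clr_cut,
        "calls": calls,
        "psgs": psgs,
        "ld": ld,
        "fst_profile": fst_profile,
        "manifest": manifest,
    }
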