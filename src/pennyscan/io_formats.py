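"""Standard-format I/O and the printed variant hard filters.

Readers return the pipeline's in-memory containers (`GenotypeMatrix`,
`VariantRecord`, `GeneModel`). Only biallelic SNPs enter the pipeline;
multi-allelic and indel records are skipped with a logged count.

Coordinate conventions: variant positions are stored 1-based as in VCF;
windows and BED output are 0-based half-open; GFF3 intervals are 1-based
inclusive as in the format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage / haplotype sentinel


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantRecord:
    """One biallelic SNP with the site annotations the hard filters test.

    ``genotypes`` holds per-sample diploid alt-allele dosage in {0, 1, 2}
    with -1 for missing; ``gq`` per-sample genotype quality (None when the
    VCF carries no GQ).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_annotations: dict = field(default_factory=dict)
    genotypes: np.ndarray | None = None
    gq: np.ndarray | None = None
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Sites x samples dosage table with population/group labels.

    ``sites`` is a DataFrame with columns chrom, pos (1-based), ref, alt and
    optionally anc (ancestral allele, for unfolded spectra). ``dosage`` is an
    int8 array (n_sites, n_samples) of alt dosages, -1 missing.
    ``haplotypes``, when present, is (n_sites, 2 * n_samples) in {0, 1} with
    columns [s0_hap0, s0_hap1, s1_hap0, ...]; haplotype pairs sum to dosage.
    """

    sites: pd.DataFrame
    samples: list[str]
    populations: np.ndarray
    groups: np.ndarray
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.haplotypes is not None:
            hap_sum = self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]
            dos = self.dosage
            ok = (dos == MISSING) | (hap_sum == dos)
            if not np.all(ok):
                raise ValueError("haplotypes inconsistent with dosages")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str | None = None, group: str | None = None) -> np.ndarray:
        """Column indices of samples in a population or group."""
        mask = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            mask &= self.populations == population
        if group is not None:
            mask &= self.groups == group
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no samples match population={population!r} group={group!r}")
        return idx

    def haplotype_columns(self, sample_idx: np.ndarray) -> np.ndarray:
        cols = np.empty(2 * sample_idx.size, dtype=int)
        cols[0::2] = 2 * sample_idx
        cols[1::2] = 2 * sample_idx + 1
        return cols

    def take_sites(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to a boolean mask or index array over sites."""
        idx = np.flatnonzero(mask_or_idx) if mask_or_idx.dtype == bool else mask_or_idx
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            populations=self.populations.copy(),
            groups=self.groups.copy(),
            dosage=self.dosage[idx].copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx].copy(),
        )


@dataclass
class GeneModel:
    """A single-transcript gene model: ordered exon and CDS intervals.

    Intervals are 1-based inclusive tuples in genomic order regardless of
    strand; transcript assembly handles the reverse complement for minus
    strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    frame: int = 0

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS interval outside exons in gene {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


# ---------------------------------------------------------------------------
# population map


def read_popmap(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a 3-column TSV (sample, population, group) into a mapping."""
    out: dict[str, tuple[str, str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{i}: expected 3 tab-separated columns")
        out[parts[0]] = (parts[1], parts[2])
    return out


def write_popmap(path: str | Path, popmap: Mapping[str, tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for sample, (pop, group) in popmap.items():
            fh.write(f"{sample}\t{pop}\t{group}\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    population_map: Mapping[str, tuple[str, str]] | str | Path,
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix + VariantRecords.

    Multi-allelic and indel records are skipped (count logged). Every sample
    in the VCF header must appear in the population map. Phased genotypes are
    collected into the haplotype table when all genotypes are phased.
    """
    from cyvcf2 import VCF

    if not isinstance(population_map, Mapping):
        population_map = read_popmap(population_map)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in population_map:
            raise ValueError(f"sample {s!r} missing from population map")
    pops = np.array([population_map[s][0] for s in samples], dtype=object)
    groups = np.array([population_map[s][1] for s in samples], dtype=object)

    rows, records, haps = [], [], []
    all_phased = True
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        gts = np.array(v.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gts], dtype=np.int8)
        a1 = np.array([g[1] for g in gts], dtype=np.int8)
        phased = all(bool(g[2]) for g in gts)
        all_phased &= phased
        dos = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        hap = np.empty(2 * len(samples), dtype=np.int8)
        hap[0::2], hap[1::2] = np.maximum(a0, 0), np.maximum(a1, 0)
        haps.append(hap)
        ann = {}
        for key in ("QD", "FS", "MQ"):
            val = v.INFO.get(key)
            if val is not None:
                ann[key] = float(val)
        aa = v.INFO.get("AA")
        gq = None
        try:
            q = v.gt_quals
            if q is not None and not np.all(q < 0):
                gq = q.astype(float)
        except Exception:
            gq = None
        rec = VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            site_annotations=ann,
            genotypes=dos,
            gq=gq,
            filter_status=v.FILTER or "PASS",
        )
        records.append(rec)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], aa))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "anc"])
    dosage = (
        np.vstack([r.genotypes for r in records])
        if records
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    hap_table = np.vstack(haps).astype(np.int8) if (haps and all_phased) else None
    matrix = GenotypeMatrix(
        sites=sites,
        samples=samples,
        populations=pops,
        groups=groups,
        dosage=dosage,
        haplotypes=hap_table,
    )
    return matrix, records


def write_vcf(
    path: str | Path,
    matrix: GenotypeMatrix,
    contig_lengths: Mapping[str, int] | None = None,
    phased: bool | None = None,
) -> None:
    """Emit a VCFv4.2 file from a GenotypeMatrix.

    Ancestral alleles (sites column ``anc``) are written as INFO/AA so
    unfolded spectra survive a round trip. Haplotypes are written phased
    when present (or as forced by ``phased``).
    """
    use_phase = matrix.haplotypes is not None if phased is None else phased
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pennyscan\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in matrix.sites["chrom"].unique():
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        has_anc = "anc" in matrix.sites.columns
        sep = "|" if use_phase else "/"
        for i, row in enumerate(matrix.sites.itertuples(index=False)):
            info = "."
            if has_anc and isinstance(row.anc, str):
                info = f"AA={row.anc}"
            gt_fields = []
            for j in range(matrix.n_samples):
                d = matrix.dosage[i, j]
                if d == MISSING:
                    gt_fields.append(f".{sep}.")
                elif use_phase and matrix.haplotypes is not None:
                    h0, h1 = matrix.haplotypes[i, 2 * j], matrix.haplotypes[i, 2 * j + 1]
                    gt_fields.append(f"{h0}{sep}{h1}")
                else:
                    gt_fields.append({0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[int(d)])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gt_fields)
                + "\n"
            )


# ---------------------------------------------------------------------------
# hard filters


def apply_hard_filters(
    records: Sequence[VariantRecord],
    qd_min: float = 4.0,
    fs_max: float = 60.0,
    mq_min: float = 40.0,
    gq_min: float = 20.0,
) -> dict[str, int]:
    """Apply the GATK-style site and genotype hard filters in place.

    A site fails when QD < qd_min OR FS > fs_max OR MQ < mq_min (strict
    inequalities, matching the VariantFiltration expression); an absent
    annotation passes its sub-predicate. Genotypes with GQ < gq_min are set
    missing, the site itself is retained. Returns counts of failed sites and
    masked genotypes.
    """
    n_fail_site = 0
    n_fail_gt = 0
    for rec in records:
        ann = rec.site_annotations
        fail = (
            ("QD" in ann and ann["QD"] < qd_min)
            or ("FS" in ann and ann["FS"] > fs_max)
            or ("MQ" in ann and ann["MQ"] < mq_min)
        )
        if fail:
            rec.filter_status = "hard_filter"
            n_fail_site += 1
        if rec.gq is not None and rec.genotypes is not None:
            low = (rec.gq < gq_min) & (rec.genotypes != MISSING)
            if np.any(low):
                rec.genotypes[low] = MISSING
                n_fail_gt += int(low.sum())
    logger.info(
        "hard filters: %d sites failed, %d genotypes masked", n_fail_site, n_fail_gt
    )
    return {"failed_sites": n_fail_site, "masked_genotypes": n_fail_gt}


def cluster_filter(
    records: Sequence[VariantRecord],
    window_bp: int = 4,
    cluster_size: int = 3,
) -> int:
    """Flag SNPs in clusters of >= cluster_size within window_bp bases.

    A run of ``cluster_size`` consecutive SNPs spanning <= ``window_bp``
    bases (inclusive of both endpoints) marks every SNP of the run as
    ``snp_cluster``. Records must be sorted by (chrom, pos). Returns the
    number of newly flagged sites.
    """
    last: tuple[str, int] | None = None
    for rec in records:
        key = (rec.chrom, rec.pos)
        if last is not None and rec.chrom == last[0] and rec.pos <= last[1]:
            raise ValueError(f"records not sorted at {rec.chrom}:{rec.pos}")
        last = key

    flagged = np.zeros(len(records), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_chrom.setdefault(rec.chrom, []).append(i)
    for idxs in by_chrom.values():
        pos = np.array([records[i].pos for i in idxs])
        for k in range(len(pos) - cluster_size + 1):
            if pos[k + cluster_size - 1] - pos[k] + 1 <= window_bp:
                flagged[idxs[k] : idxs[k + cluster_size - 1] + 1] = True
    n_new = 0
    for i, rec in enumerate(records):
        if flagged[i] and rec.filter_status == "PASS":
            rec.filter_status = "snp_cluster"
            n_new += 1
        elif flagged[i]:
            rec.filter_status += ";snp_cluster"
    logger.info("cluster filter: %d sites flagged", int(flagged.sum()))
    return n_new


def select_pass(matrix: GenotypeMatrix, records: Sequence[VariantRecord]) -> GenotypeMatrix:
    """Matrix restricted to PASS sites, with filter-masked genotypes applied.

    ``records`` must be row-aligned with ``matrix`` (as returned by
    ``read_vcf``); genotype masking done by ``apply_hard_filters`` is
    propagated into the dosage table.
    """
    if len(records) != matrix.n_sites:
        raise ValueError("records not aligned with matrix sites")
    keep = np.array([r.filter_status == "PASS" for r in records])
    dosage = np.vstack([r.genotypes for r in records]).astype(np.int8)
    haps = matrix.haplotypes
    if haps is not None and np.any(dosage == MISSING):
        haps = None  # phase information lost for masked genotypes
    out = GenotypeMatrix(
        sites=matrix.sites.copy(),
        samples=list(matrix.samples),
        populations=matrix.populations.copy(),
        groups=matrix.groups.copy(),
        dosage=dosage,
        haplotypes=haps,
    )
    return out.take_sites(keep)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / tables


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(path: str | Path, intervals: Iterable[tuple], extra_header: list[str] | None = None) -> None:
    """Write (chrom, start, end, *rest) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        if extra_header:
            fh.write("#" + "\t".join(["chrom", "start", "end"] + extra_header) + "\n")
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    """Tab-separated table with a header row."""
    table.to_csv(path, sep="\t", index=False)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/exon/CDS hierarchy into GeneModels.

    One model per mRNA; the first transcript's id is kept as gene id when the
    gene has a single transcript (the usual case here).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        for parent in parents:
            exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
            cds_feats = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
            cds = [(f.start, f.end) for f in cds_feats]
            if not exons:
                exons = list(cds)
            if cds_feats:
                first = cds_feats[0] if gene.strand != "-" else cds_feats[-1]
                frame = int(first.frame) if first.frame not in (None, ".") else 0
            else:
                frame = 0
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    cds=cds,
                    frame=frame,
                )
            )
    return models


def write_gff(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            lo, hi = gm.span
            base = f"{gm.chrom}\tpennyscan"
            fh.write(f"{base}\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n")
            mrna_id = f"{gm.gene_id}.t1"
            fh.write(
                f"{base}\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\t"
                f"ID={mrna_id};Parent={gm.gene_id}\n"
            )
            for s, e in gm.exons:
                fh.write(f"{base}\texon\t{s}\t{e}\t.\t{gm.strand}\t.\tParent={mrna_id}\n")
            cds_in_tx = gm.cds if gm.strand != "-" else list(reversed(gm.cds))
            phase = gm.frame
            for s, e in cds_in_tx:
                fh.write(f"{base}\tCDS\t{s}\t{e}\t.\t{gm.strand}\t{phase}\tParent={mrna_id}\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
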