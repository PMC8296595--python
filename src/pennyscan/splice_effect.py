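"""Splice-donor disruption, intron retention and premature stop codons.

Detects variants that hit base +1/+2 of a canonical GT donor (transcription
orientation), rebuilds the transcript with the disrupted intron retained,
and reports the first in-frame stop. The HGVS-like label places the variant
by the CDS length upstream of the intron (e.g. ``c.450+1 G>C``). The stop
offset counts nucleotides strictly after the mutated base up to the first
base of the stop codon; the convention is recorded in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from pennyscan.differentiation import group_fst_profile
from pennyscan.diversity_stats import WindowSpec
from pennyscan.io_formats import GeneModel, GenotypeMatrix
from pennyscan.synthetic_data import STOPS, revcomp

STOP_CONVENTION = "offset_to_first_base_of_stop"


@dataclass
class Intron:
    index: int  # 1-based, transcription order
    start: int  # genomic, 1-based inclusive
    end: int
    donor: str  # first 2 intron bases, transcription orientation
    acceptor: str  # last 2 intron bases, transcription orientation


@dataclass
class SpliceEffect:
    gene_id: str
    intron_index: int
    variant: tuple[str, int, str, str]  # chrom, pos, ref, alt (genomic strand)
    label: str
    consequence: str  # donor_disrupted | acceptor_disrupted | none
    cds_upstream: int = 0
    intron_offset: int = 0
    retained_transcript: str | None = None
    stop_found: bool = False
    stop_codon: str | None = None
    stop_offset_nt: int | None = None
    truncated_protein: str | None = None


def _gene_sequence(genome: Mapping[str, str], gene: GeneModel) -> str:
    if gene.chrom not in genome:
        raise ValueError(f"chromosome {gene.chrom} absent from genome")
    return genome[gene.chrom]


def find_canonical_introns(gene: GeneModel, genome: Mapping[str, str]) -> list[Intron]:
    """Introns between consecutive exons, with strand-aware dinucleotides."""
    seq = _gene_sequence(genome, gene)
    lo, hi = gene.span
    if hi > len(seq):
        raise ValueError(f"gene {gene.gene_id} extends past chromosome end")
    genomic = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        genomic.append((e1 + 1, s2 - 1))
    if gene.strand == "-":
        ordered = list(reversed(genomic))
    else:
        ordered = genomic
    out = []
    for i, (s, e) in enumerate(ordered, start=1):
        if gene.strand == "-":
            donor = revcomp(seq[e - 2 : e])
            acceptor = revcomp(seq[s - 1 : s + 1])
        else:
            donor = seq[s - 1 : s + 1]
            acceptor = seq[e - 2 : e]
        out.append(Intron(index=i, start=s, end=e, donor=donor, acceptor=acceptor))
    return out


def _cds_upstream_of_intron(gene: GeneModel, intron: Intron) -> int:
    """Total CDS length transcriptionally upstream of the intron."""
    total = 0
    for cs, ce in gene.cds:
        if gene.strand == "-":
            if ce > intron.end:
                total += ce - max(cs, intron.end + 1) + 1
        else:
            if cs < intron.start:
                total += min(ce, intron.start - 1) - cs + 1
    return total


def donor_disruption(
    variants: Sequence[tuple[str, int, str, str]],
    introns: list[Intron],
    gene: GeneModel,
    include_acceptor: bool = False,
) -> list[SpliceEffect]:
    """Flag variants at intron positions +1/+2 (and optionally acceptor -2/-1).

    ``variants`` are (chrom, pos, ref, alt) on the genomic strand. The label
    uses transcript-orientation alleles.
    """
    effects = []
    for chrom, pos, ref, alt in variants:
        if chrom != gene.chrom:
            continue
        for intron in introns:
            if gene.strand == "-":
                offset = intron.end - pos + 1
                acc_offset = pos - intron.start + 1
                t_ref, t_alt = revcomp(ref), revcomp(alt)
            else:
                offset = pos - intron.start + 1
                acc_offset = intron.end - pos + 1
                t_ref, t_alt = ref, alt
            cds_up = _cds_upstream_of_intron(gene, intron)
            if offset in (1, 2):
                label = f"c.{cds_up}+{offset} {t_ref}>{t_alt}"
                effects.append(
                    SpliceEffect(
                        gene_id=gene.gene_id,
                        intron_index=intron.index,
                        variant=(chrom, pos, ref, alt),
                        label=label,
                        consequence="donor_disrupted",
                        cds_upstream=cds_up,
                        intron_offset=offset,
                    )
                )
            elif include_acceptor and acc_offset in (1, 2):
                label = f"c.{cds_up + 1}-{acc_offset} {t_ref}>{t_alt}"
                effects.append(
                    SpliceEffect(
                        gene_id=gene.gene_id,
                        intron_index=intron.index,
                        variant=(chrom, pos, ref, alt),
                        label=label,
                        consequence="acceptor_disrupted",
                        cds_upstream=cds_up,
                        intron_offset=-acc_offset,
                    )
                )
    return effects


def _transcript_with_retained_intron(
    gene: GeneModel, genome: Mapping[str, str], intron_index: int,
    variant: tuple[str, int, str, str] | None,
) -> tuple[str, int]:
    """(transcript sequence with intron retained and alt applied,
    transcript position of the intron's first base), both 1-based."""
    seq = _gene_sequence(genome, gene)
    if variant is not None:
        chrom, pos, ref, alt = variant
        if seq[pos - 1] != ref:
            raise ValueError(f"reference mismatch at {chrom}:{pos}")
        seq = seq[: pos - 1] + alt + seq[pos:]
    introns = find_canonical_introns(gene, {gene.chrom: seq})
    target = introns[intron_index - 1]
    exons_tx = gene.exons if gene.strand != "-" else list(reversed(gene.exons))

    parts = []
    intron_tx_pos = None
    for i, (s, e) in enumerate(exons_tx):
        piece = seq[s - 1 : e]
        if gene.strand == "-":
            piece = revcomp(piece)
        parts.append(piece)
        if i + 1 == intron_index:
            intron_tx_pos = sum(len(p) for p in parts) + 1
            ipiece = seq[target.start - 1 : target.end]
            if gene.strand == "-":
                ipiece = revcomp(ipiece)
            parts.append(ipiece)
    assert intron_tx_pos is not None
    return "".join(parts), intron_tx_pos


def retained_intron_effect(
    gene: GeneModel,
    genome: Mapping[str, str],
    effect: SpliceEffect,
) -> SpliceEffect:
    """Complete a donor-disruption call with the retained-intron transcript.

    Translation proceeds in the CDS frame across the retained intron; the
    first in-frame stop at or after the mutated base is reported with its
    offset (nucleotides strictly after the mutated base to the stop codon's
    first base) and the truncated protein. When the frame never meets a
    stop, ``stop_found`` stays False and the full read-through protein is
    returned.
    """
    if effect.consequence != "donor_disrupted":
        raise ValueError("retained-intron modelling applies to donor disruptions")
    transcript, intron_tx_pos = _transcript_with_retained_intron(
        gene, genome, effect.intron_index, effect.variant
    )
    mut_tx_pos = intron_tx_pos + effect.intron_offset - 1
    # CDS start offset within the transcript (toy genes are fully coding;
    # general models translate from the first CDS base)
    cds_start = _cds_start_in_transcript(gene, effect.intron_index)
    coding = transcript[cds_start:]
    mut_cds_pos = mut_tx_pos - cds_start  # 1-based within coding sequence

    effect.retained_transcript = transcript
    protein = []
    for i in range(0, len(coding) - 2, 3):
        codon = coding[i : i + 3]
        if codon in STOPS and i + 1 >= mut_cds_pos:
            effect.stop_found = True
            effect.stop_codon = codon
            effect.stop_offset_nt = (i + 1) - mut_cds_pos
            break
        protein.append(_translate_codon(codon))
    effect.truncated_protein = "".join(protein)
    return effect


def _cds_start_in_transcript(gene: GeneModel, retained_intron_index: int) -> int:
    """0-based offset of the first CDS base in the exonic transcript.

    The retained intron lies downstream of the CDS start for donor
    disruptions with cds_upstream > 0, so the offset is unaffected by the
    retention.
    """
    exons_tx = gene.exons if gene.strand != "-" else list(reversed(gene.exons))
    cds = gene.cds
    if not cds:
        return 0
    if gene.strand == "-":
        cds_first = max(e for _, e in cds)
        off = 0
        for s, e in exons_tx:
            if s <= cds_first <= e:
                return off + (e - cds_first) + gene.frame
            off += e - s + 1
    else:
        cds_first = min(s for s, _ in cds)
        off = 0
        for s, e in exons_tx:
            if s <= cds_first <= e:
                return off + (cds_first - s) + gene.frame
            off += e - s + 1
    raise ValueError(f"CDS start outside exons in {gene.gene_id}")


_CODON_TABLE: dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
    return _CODON_TABLE.get(codon, "X")


def analyze_gene(
    gene: GeneModel,
    genome: Mapping[str, str],
    variants: Sequence[tuple[str, int, str, str]],
) -> list[SpliceEffect]:
    """Donor-disruption calls for one gene, completed with retention effects."""
    introns = find_canonical_introns(gene, genome)
    effects = donor_disruption(variants, introns, gene)
    return [retained_intron_effect(gene, genome, e) for e in effects]


def effects_table(effects: list[SpliceEffect]) -> pd.DataFrame:
    rows = []
    for e in effects:
        chrom, pos, ref, alt = e.variant
        rows.append(
            {
                "gene": e.gene_id,
                "intron": e.intron_index,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "label": e.label,
                "consequence": e.consequence,
                "stop_found": e.stop_found,
                "stop_codon": e.stop_codon or "",
                "stop_offset_nt": e.stop_offset_nt if e.stop_offset_nt is not None else "",
                "protein_length_aa": len(e.truncated_protein or ""),
                "stop_offset_convention": STOP_CONVENTION,
            }
        )
    return pd.DataFrame(rows)


def region_fst_profile(
    matrix: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    size: int = 20_000,
    step: int = 10_000,
    group_a: str = "HG",
    group_b: str = "LG",
) -> pd.DataFrame:
    """Windowed pooled-group F_ST profile across a genomic region."""
    windows = []
    s = start
    while s + size <= end:
        windows.append(WindowSpec(chrom, s, s + size))
        s += step
    if not windows and end - start > 0:
        windows = [WindowSpec(chrom, start, end)]
    return group_fst_profile(matrix, windows, group_a=group_a, group_b=group_b)
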