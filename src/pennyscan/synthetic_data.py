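"""Synthetic cohorts, sweeps, toy gene models and LTR pairs.

The generator emulates the study design the pipeline targets: four diploid
populations in two elevation groups ((H1,H2),(L1,L2)), ten highly selfing
individuals each, genome-wide diversity around theta_pi ~ 5e-4 per bp, a
neutral background plus optional localized sweeps confined to one group.

Linkage is modelled as independent non-recombining blocks (default 2.5 kb,
the genealogy correlation scale ~1/(4*Ne*r) at the default Ne and
recombination rate):
within a block a single structured-coalescent genealogy is drawn over the
deme hierarchy, mutations fall on branches as a Poisson process, and blocks
are mutually independent. This is adequate for window statistics and
qualitative LD decay; it does not reproduce fine-scale recombination
structure.

Selfing is modelled through the equilibrium inbreeding coefficient
F' = F/(2-F): with that probability an individual's two haplotypes are
copies of a single sampled lineage (instant within-individual coalescence),
otherwise they enter the genealogy independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from pennyscan.io_formats import GeneModel, GenotypeMatrix

STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SweepSpec:
    """A hard sweep centred at ``center`` (bp) restricted to ``focal_group``.

    ``alpha`` parameterizes the per-bp escape probability
    p_e(d) = 1 - exp(-alpha * r_rec * d): small alpha means little
    recombinational escape (a strong, wide sweep footprint), alpha -> inf
    recovers neutrality.
    """

    center: int
    alpha: float = 1e3
    focal_group: str = "HG"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the target study design: 2 high + 2 low elevation
    demes, 10 diploids each, mutation rate 7e-9 per site per generation,
    1-year generations, high selfing, and deme sizes / split times tuned so
    per-population diversity sits at the observed scale (theta = 4*N*mu
    ~ 5e-4 per bp) with moderate between-group differentiation.
    """

    seed: int = 0
    demes: list[tuple[str, str, int]] = field(
        default_factory=lambda: [
            ("MK", "HG", 10),
            ("ZG", "HG", 10),
            ("HF", "LG", 10),
            ("XA", "LG", 10),
        ]
    )
    deme_size: float = 18_000.0
    split_within: float = 2_000.0
    split_groups: float = 8_000.0
    migration: float = 0.0
    mu: float = 7e-9
    generation_time: float = 1.0
    selfing: float = 0.8
    chrom_length: int = 1_000_000
    block_length: int = 2_500
    chrom_name: str = "Chr1"
    r_rec: float = 1e-8
    sweep: SweepSpec | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.selfing < 1.0):
            raise ValueError("selfing coefficient must be in [0, 1)")
        if self.migration < 0:
            raise ValueError("migration rate must be >= 0")
        if self.split_within <= 0 or self.split_groups <= 0:
            raise ValueError("split times must be > 0")
        if self.split_within >= self.split_groups:
            raise ValueError(
                "within-group split time must be younger than the group split"
            )
        if self.block_length > self.chrom_length:
            raise ValueError("block length exceeds chromosome length")

    @property
    def selfing_equilibrium(self) -> float:
        """F' = F/(2-F), the probability both haplotypes share one lineage."""
        return self.selfing / (2.0 - self.selfing)

    def sample_names(self) -> list[str]:
        return [f"{name}_{i:02d}" for name, _, n in self.demes for i in range(n)]

    def popmap(self) -> dict[str, tuple[str, str]]:
        out = {}
        for name, group, n in self.demes:
            for i in range(n):
                out[f"{name}_{i:02d}"] = (name, group)
        return out


# ---------------------------------------------------------------------------
# structured coalescent


def _simulate_block_tree(cfg: SimConfig, rng: np.random.Generator):
    """One genealogy over all sampled haplotypes of one block.

    Returns (times, children, leaf_columns): node times in generations,
    children lists (empty for leaves), and for each leaf the haplotype
    columns it carries (two columns for a selfed individual's collapsed
    pair).
    """
    fprime = cfg.selfing_equilibrium
    times: list[float] = []
    children: list[list[int]] = []
    leaf_columns: list[list[int]] = []
    active: list[int] = []  # node ids
    deme_of: dict[int, str] = {}

    col = 0
    for name, _group, n_dip in cfg.demes:
        for _ in range(n_dip):
            if rng.random() < fprime:
                nid = len(times)
                times.append(0.0)
                children.append([])
                leaf_columns.append([col, col + 1])
                active.append(nid)
                deme_of[nid] = name
            else:
                for c in (col, col + 1):
                    nid = len(times)
                    times.append(0.0)
                    children.append([])
                    leaf_columns.append([c])
                    active.append(nid)
                    deme_of[nid] = name
            col += 2

    group_of = {name: group for name, group, _ in cfg.demes}
    boundaries = [cfg.split_within, cfg.split_groups, math.inf]
    phase = 0
    t = 0.0
    N = cfg.deme_size

    def relabel(phase: int) -> None:
        for nid in active:
            if phase == 1:
                deme_of[nid] = group_of.get(deme_of[nid], deme_of[nid])
            else:
                deme_of[nid] = "ANC"

    while len(active) > 1:
        counts: dict[str, int] = {}
        for nid in active:
            counts[deme_of[nid]] = counts.get(deme_of[nid], 0) + 1
        coal_rates = {d: k * (k - 1) / 2.0 / (2.0 * N) for d, k in counts.items()}
        n_demes = len(counts)
        mig_rate = len(active) * cfg.migration if n_demes > 1 else 0.0
        total = sum(coal_rates.values()) + mig_rate
        if total <= 0.0:
            t = boundaries[phase]
            phase += 1
            relabel(phase)
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= boundaries[phase]:
            t = boundaries[phase]
            phase += 1
            relabel(phase)
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        event_deme = None
        for d, rate in coal_rates.items():
            acc += rate
            if u < acc:
                event_deme = d
                break
        if event_deme is not None:
            pool = [nid for nid in active if deme_of[nid] == event_deme]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[i], pool[j]
            nid = len(times)
            times.append(t)
            children.append([a, b])
            leaf_columns.append([])
            active.remove(a)
            active.remove(b)
            del deme_of[a], deme_of[b]
            active.append(nid)
            deme_of[nid] = event_deme
        else:
            nid = active[rng.integers(len(active))]
            others = [d for d in counts if d != deme_of[nid]]
            deme_of[nid] = others[rng.integers(len(others))]
    return times, children, leaf_columns


def _columns_under(node: int, children, leaf_columns, cache) -> list[int]:
    if cache[node] is None:
        if not children[node]:
            cache[node] = leaf_columns[node]
        else:
            out: list[int] = []
            for ch in children[node]:
                out.extend(_columns_under(ch, children, leaf_columns, cache))
            cache[node] = out
    return cache[node]


_BASES = np.array(list("ACGT"))


def simulate_neutral_cohort(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate a phased neutral cohort under the block-coalescent model.

    Each ``block_length`` segment receives an independent genealogy over the
    deme hierarchy ((H demes), (L demes)) with symmetric migration, and
    Poisson(mu * branch * block_length) mutations at distinct uniform
    positions. Ancestral alleles become REF, so the ``anc`` column equals
    REF and the unfolded spectrum is the ALT-count spectrum. Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * sum(n for _, _, n in cfg.demes)
    n_blocks = cfg.chrom_length // cfg.block_length

    all_pos: list[np.ndarray] = []
    all_hap: list[np.ndarray] = []
    for b in range(n_blocks):
        times, children, leaf_cols = _simulate_block_tree(cfg, rng)
        n_nodes = len(times)
        root = n_nodes - 1
        parent = np.full(n_nodes, -1, dtype=int)
        for v in range(n_nodes):
            for ch in children[v]:
                parent[ch] = v
        # mutation counts per node branch
        branch = np.zeros(n_nodes)
        for v in range(n_nodes - 1):
            branch[v] = times[parent[v]] - times[v]
        nmut = rng.poisson(cfg.mu * cfg.block_length * branch)
        total = int(nmut.sum())
        if total == 0:
            continue
        total = min(total, cfg.block_length)
        positions = rng.choice(cfg.block_length, size=total, replace=False)
        cache = [None] * n_nodes
        hap_block = np.zeros((total, n_hap), dtype=np.int8)
        k = 0
        for v in range(n_nodes - 1):
            for _ in range(int(nmut[v])):
                if k >= total:
                    break
                cols = _columns_under(v, children, leaf_cols, cache)
                hap_block[k, cols] = 1
                k += 1
        order = np.argsort(positions[:k], kind="stable")
        all_pos.append(positions[:k][order] + b * cfg.block_length + 1)
        all_hap.append(hap_block[:k][order])

    if all_pos:
        pos = np.concatenate(all_pos)
        hap = np.vstack(all_hap)
    else:
        pos = np.zeros(0, dtype=int)
        hap = np.zeros((0, n_hap), dtype=np.int8)

    ref_idx = rng.integers(0, 4, size=pos.size)
    alt_shift = rng.integers(1, 4, size=pos.size)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    sites = pd.DataFrame(
        {
            "chrom": cfg.chrom_name,
            "pos": pos.astype(int),
            "ref": ref,
            "alt": alt,
            "anc": ref,
        }
    )
    dosage = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    return GenotypeMatrix(
        sites=sites,
        samples=cfg.sample_names(),
        populations=np.array(
            [name for name, _, n in cfg.demes for _ in range(n)], dtype=object
        ),
        groups=np.array(
            [group for _, group, n in cfg.demes for _ in range(n)], dtype=object
        ),
        dosage=dosage,
        haplotypes=hap,
    )


def inject_sweep(
    matrix: GenotypeMatrix,
    center: int,
    alpha: float,
    r_rec: float,
    focal_group: str,
    seed: int,
) -> GenotypeMatrix:
    """Overlay a star-genealogy hard sweep on the focal group's haplotypes.

    One focal haplotype is chosen as the sweeping haplotype. At each site at
    distance d from ``center``, every focal haplotype independently escapes
    with probability p_e = 1 - exp(-alpha * r_rec * d) and keeps its allele;
    otherwise its allele is overwritten by the sweeper's. Non-focal samples
    are untouched. Deterministic under ``seed``.
    """
    if alpha <= 0:
        raise ValueError("sweep alpha must be > 0")
    if matrix.haplotypes is None:
        raise ValueError("sweep injection requires phased haplotypes")
    rng = np.random.default_rng(seed)
    focal = matrix.sample_indices(group=focal_group)
    cols = matrix.haplotype_columns(focal)
    hap = matrix.haplotypes.copy()
    sweeper = cols[rng.integers(cols.size)]
    d = np.abs(matrix.sites["pos"].to_numpy() - center).astype(float)
    p_esc = 1.0 - np.exp(-alpha * r_rec * d)
    escape = rng.random((matrix.n_sites, cols.size)) < p_esc[:, None]
    sweep_alleles = hap[:, sweeper].copy()
    block = hap[:, cols]
    hap[:, cols] = np.where(escape, block, sweep_alleles[:, None])
    dosage = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    return GenotypeMatrix(
        sites=matrix.sites.copy(),
        samples=list(matrix.samples),
        populations=matrix.populations.copy(),
        groups=matrix.groups.copy(),
        dosage=dosage,
        haplotypes=hap,
    )


def simulate_cohort(cfg: SimConfig) -> GenotypeMatrix:
    """Neutral cohort plus the configured sweep, if any."""
    matrix = simulate_neutral_cohort(cfg)
    if cfg.sweep is not None:
        matrix = inject_sweep(
            matrix,
            center=cfg.sweep.center,
            alpha=cfg.sweep.alpha,
            r_rec=cfg.r_rec,
            focal_group=cfg.sweep.focal_group,
            seed=cfg.seed + 1,
        )
    return matrix


# ---------------------------------------------------------------------------
# toy multi-exon gene with a splice-donor variant


@dataclass
class ToyGeneSpec:
    """Design of the toy gene carrying a donor-disrupting G>C variant.

    The disrupted intron's interior is engineered so the retained-intron
    reading frame meets its first stop codon (TGA) with the stop's first
    base exactly ``stop_offset`` nucleotides after the mutated donor base.
    Defaults reproduce the canonical case: 450 nt of CDS upstream of the
    disrupted (fifth) intron and a stop 51 nt downstream of the mutation.
    """

    exon_lengths: list[int] = field(
        default_factory=lambda: [100, 90, 80, 100, 80, 120, 150]
    )
    intron_lengths: list[int] = field(default_factory=lambda: [90] * 6)
    disrupted_intron: int = 5  # 1-based index in transcription order
    stop_offset: int = 51
    flank: int = 500
    strand: str = "+"
    chrom_name: str = "ChrT"
    gene_id: str = "toyFLC"
    n_per_pop: int = 5
    seed: int = 2024

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if not (1 <= self.disrupted_intron <= len(self.intron_lengths)):
            raise ValueError("disrupted intron index out of range")
        if sum(self.exon_lengths) % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")
        # mutated base sits at transcript position cds_upstream + 1; the stop
        # codon's first base must land on a codon boundary of the CDS frame
        if (self.cds_upstream + self.stop_offset) % 3 != 0:
            raise ValueError("designed stop offset is not in frame")
        if self.intron_lengths[self.disrupted_intron - 1] < self.stop_offset + 5:
            raise ValueError("disrupted intron too short for the designed stop")

    @property
    def cds_upstream(self) -> int:
        """CDS length upstream of the disrupted intron (450 by default)."""
        return sum(self.exon_lengths[: self.disrupted_intron])


@dataclass
class ToyGene:
    genome: dict[str, str]
    gene: GeneModel
    matrix: GenotypeMatrix
    variant: tuple[str, int, str, str]  # chrom, pos, ref, alt (genomic strand)
    popmap: dict[str, tuple[str, str]]
    spec: ToyGeneSpec


def _toy_cds(rng: np.random.Generator, length: int) -> str:
    n_codon = length // 3
    codons = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))] for _ in range(n_codon - 1)
    ]
    return "".join(codons) + "TAA"


def _plain_intron(rng: np.random.Generator, length: int) -> str:
    interior = "".join("ACGT"[rng.integers(4)] for _ in range(length - 4))
    return "GT" + interior + "AG"


def _disrupted_intron_seq(spec: ToyGeneSpec) -> str:
    length = spec.intron_lengths[spec.disrupted_intron - 1]
    # transcript frame: mutated G at position cds_upstream+1, a codon start
    # boundary is at cds_upstream+1 (since cds_upstream % 3 may be nonzero,
    # the constraint checked in the spec is on the stop's first base).
    pre_stop = spec.stop_offset - 2  # bases between "GT" and the stop codon
    tail = length - 2 - pre_stop - 3 - 2
    return "GT" + "C" * pre_stop + "TGA" + "C" * tail + "AG"


def make_toy_gene(spec: ToyGeneSpec | None = None) -> ToyGene:
    """Build genome FASTA, gene model and cohort VCF matrix for the toy gene.

    The donor variant (G>C at position +1 of the disrupted intron) is fixed
    for the alternate allele in all HG samples and fixed reference in LG.
    All intron boundaries are canonical GT..AG in the reference.
    """
    spec = spec or ToyGeneSpec()
    rng = np.random.default_rng(spec.seed)

    cds = _toy_cds(rng, sum(spec.exon_lengths))
    exon_seqs = []
    off = 0
    for L in spec.exon_lengths:
        exon_seqs.append(cds[off : off + L])
        off += L
    intron_seqs = []
    for i, L in enumerate(spec.intron_lengths, start=1):
        if i == spec.disrupted_intron:
            intron_seqs.append(_disrupted_intron_seq(spec))
        else:
            intron_seqs.append(_plain_intron(rng, L))

    flank5 = "".join("ACGT"[rng.integers(4)] for _ in range(spec.flank))
    flank3 = "".join("ACGT"[rng.integers(4)] for _ in range(spec.flank))
    body = []
    exons: list[tuple[int, int]] = []
    pos = spec.flank + 1
    variant_pos_plus = None
    for i, ex in enumerate(exon_seqs):
        exons.append((pos, pos + len(ex) - 1))
        body.append(ex)
        pos += len(ex)
        if i < len(intron_seqs):
            if i + 1 == spec.disrupted_intron:
                variant_pos_plus = pos  # first base of the intron (the G)
            body.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    seq_plus = flank5 + "".join(body) + flank3
    assert variant_pos_plus is not None
    assert seq_plus[variant_pos_plus - 1] == "G"

    if spec.strand == "+":
        genome_seq = seq_plus
        gene_exons = exons
        var_pos, var_ref, var_alt = variant_pos_plus, "G", "C"
    else:
        L = len(seq_plus)
        genome_seq = revcomp(seq_plus)
        gene_exons = sorted((L - e + 1, L - s + 1) for s, e in exons)
        var_pos, var_ref, var_alt = L - variant_pos_plus + 1, "C", "G"

    gene = GeneModel(
        gene_id=spec.gene_id,
        chrom=spec.chrom_name,
        strand=spec.strand,
        exons=gene_exons,
        cds=list(gene_exons),
        frame=0,
    )

    pops = [("H1", "HG"), ("H2", "HG"), ("L1", "LG"), ("L2", "LG")]
    samples, pop_labels, group_labels = [], [], []
    for pop, group in pops:
        for i in range(spec.n_per_pop):
            samples.append(f"{pop}_{i:02d}")
            pop_labels.append(pop)
            group_labels.append(group)
    dosage = np.array(
        [[2 if g == "HG" else 0 for g in group_labels]], dtype=np.int8
    )
    hap = np.repeat(dosage // 2, 2, axis=1).astype(np.int8)
    sites = pd.DataFrame(
        {
            "chrom": [spec.chrom_name],
            "pos": [var_pos],
            "ref": [var_ref],
            "alt": [var_alt],
            "anc": [var_ref],
        }
    )
    matrix = GenotypeMatrix(
        sites=sites,
        samples=samples,
        populations=np.array(pop_labels, dtype=object),
        groups=np.array(group_labels, dtype=object),
        dosage=dosage,
        haplotypes=hap,
    )
    popmap = {s: (p, g) for s, p, g in zip(samples, pop_labels, group_labels)}
    return ToyGene(
        genome={spec.chrom_name: genome_seq},
        gene=gene,
        matrix=matrix,
        variant=(spec.chrom_name, var_pos, var_ref, var_alt),
        popmap=popmap,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# LTR pairs of known age


def make_ltr_pairs(
    n_pairs: int,
    ages_years: float | Sequence[float],
    r: float = 7e-9,
    ltr_length: int = 2000,
    seed: int = 0,
) -> dict[str, str]:
    """FASTA-ready 5'/3' LTR pairs whose expected JC69 distance is 2*r*T.

    Both copies of each pair evolve independently from a random ancestor for
    T years at substitution rate ``r`` under JC69, so the expected pairwise
    distance is K = 2 r T. Records are named ``<id>_5ltr`` / ``<id>_3ltr``.
    """
    ages = np.broadcast_to(np.asarray(ages_years, dtype=float), (n_pairs,))
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    p_pair = 0.75 * (1.0 - np.exp(-(8.0 / 3.0) * r * ages))
    if np.any(p_pair >= 0.75 - 1e-12):
        raise ValueError("age implies JC69 saturation (expected p >= 0.75)")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i, T in enumerate(ages):
        anc = rng.integers(0, 4, size=ltr_length)
        p_one = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * r * T))
        copies = []
        for _ in range(2):
            mut = rng.random(ltr_length) < p_one
            shift = rng.integers(1, 4, size=ltr_length)
            seq = np.where(mut, (anc + shift) % 4, anc)
            copies.append("".join(_BASES[seq]))
        out[f"ltr{i:04d}_5ltr"] = copies[0]
        out[f"ltr{i:04d}_3ltr"] = copies[1]
    return out
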