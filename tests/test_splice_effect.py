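"""Donor-disruption detection, intron retention, premature stops, strand symmetry."""

import numpy as np
import pytest

from pennyscan.diversity_stats import make_windows
from pennyscan.io_formats import GeneModel
from pennyscan.splice_effect import (
    analyze_gene,
    donor_disruption,
    find_canonical_introns,
    region_fst_profile,
    retained_intron_effect,
)
from pennyscan.synthetic_data import ToyGeneSpec, make_toy_gene, revcomp

from conftest import matrix_from_haplotypes


def translate_oracle(seq):
    """Direct codon-table translation up to (excluding) the first stop."""
    from Bio.Seq import Seq

    aa = str(Seq(seq[: len(seq) // 3 * 3]).translate(to_stop=True))
    return aa


class TestIntrons:
    def test_toy_gene_has_six_canonical_introns(self, toy_gene_plus):
        introns = find_canonical_introns(toy_gene_plus.gene, toy_gene_plus.genome)
        assert len(introns) == 6
        assert all(i.donor == "GT" and i.acceptor == "AG" for i in introns)

    def test_minus_strand_dinucleotides_from_reverse_complement(self, toy_gene_minus):
        introns = find_canonical_introns(toy_gene_minus.gene, toy_gene_minus.genome)
        assert all(i.donor == "GT" and i.acceptor == "AG" for i in introns)

    def test_single_exon_gene_has_no_introns(self):
        gene = GeneModel("g1", "c", "+", [(1, 30)], [(1, 30)])
        assert find_canonical_introns(gene, {"c": "A" * 40}) == []

    def test_exon_past_chromosome_end_rejected(self):
        gene = GeneModel("g1", "c", "+", [(1, 100)], [(1, 100)])
        with pytest.raises(ValueError, match="past"):
            find_canonical_introns(gene, {"c": "A" * 50})


class TestDonorDisruption:
    def test_default_toy_gene_label(self, toy_gene_plus):
        effects = analyze_gene(
            toy_gene_plus.gene, toy_gene_plus.genome, [toy_gene_plus.variant]
        )
        assert len(effects) == 1
        assert effects[0].label == "c.450+1 G>C"
        assert effects[0].consequence == "donor_disrupted"
        assert effects[0].intron_index == 5

    def test_variant_at_plus_three_is_not_a_donor_hit(self, toy_gene_plus):
        chrom, pos, _, _ = toy_gene_plus.variant
        introns = find_canonical_introns(toy_gene_plus.gene, toy_gene_plus.genome)
        base = toy_gene_plus.genome[chrom][pos + 1]
        alt = "A" if base != "A" else "C"
        hits = donor_disruption(
            [(chrom, pos + 2, base, alt)], introns, toy_gene_plus.gene
        )
        assert hits == []

    def test_acceptor_mode_flags_minus_one_change(self, toy_gene_plus):
        introns = find_canonical_introns(toy_gene_plus.gene, toy_gene_plus.genome)
        intron = introns[0]
        chrom = toy_gene_plus.gene.chrom
        g_base = toy_gene_plus.genome[chrom][intron.end - 1]  # the G of ..AG
        hits = donor_disruption(
            [(chrom, intron.end, g_base, "T")],
            introns,
            toy_gene_plus.gene,
            include_acceptor=True,
        )
        assert [h.consequence for h in hits] == ["acceptor_disrupted"]


class TestRetention:
    def test_stop_offset_51(self, toy_gene_plus):
        effect = analyze_gene(
            toy_gene_plus.gene, toy_gene_plus.genome, [toy_gene_plus.variant]
        )[0]
        assert effect.stop_found
        assert effect.stop_codon == "TGA"
        assert effect.stop_offset_nt == 51

    def test_designed_offset_30_detected_as_30(self):
        toy = make_toy_gene(ToyGeneSpec(stop_offset=30))
        effect = analyze_gene(toy.gene, toy.genome, [toy.variant])[0]
        assert effect.stop_offset_nt == 30

    def test_truncated_protein_matches_codon_table_oracle(self, toy_gene_plus):
        effect = analyze_gene(
            toy_gene_plus.gene, toy_gene_plus.genome, [toy_gene_plus.variant]
        )[0]
        assert effect.truncated_protein == translate_oracle(effect.retained_transcript)
        assert len(effect.truncated_protein) == (450 + 51) // 3

    def test_strand_symmetry(self, toy_gene_plus, toy_gene_minus):
        """Reverse-complemented genome + flipped strand: identical effect."""
        eff_p = analyze_gene(
            toy_gene_plus.gene, toy_gene_plus.genome, [toy_gene_plus.variant]
        )[0]
        eff_m = analyze_gene(
            toy_gene_minus.gene, toy_gene_minus.genome, [toy_gene_minus.variant]
        )[0]
        assert eff_p.label == eff_m.label
        assert eff_p.stop_offset_nt == eff_m.stop_offset_nt
        assert eff_p.retained_transcript == eff_m.retained_transcript
        assert eff_p.truncated_protein == eff_m.truncated_protein

    def test_label_cds_position_matches_exon_bookkeeping(self, toy_gene_plus):
        spec = toy_gene_plus.spec
        effect = analyze_gene(
            toy_gene_plus.gene, toy_gene_plus.genome, [toy_gene_plus.variant]
        )[0]
        expected = sum(spec.exon_lengths[: spec.disrupted_intron])
        assert effect.cds_upstream == expected

    def test_frame_preserving_stopless_intron_reads_through(self):
        """An in-frame intron with no stop: no premature stop is reported."""
        # 2 exons of clean codons, 9-bp stop-free intron, no terminal stop
        exon1, exon2 = "ATGGCTGCA", "GCAGCTGCC"
        intron = "GTCCCCCAG"
        seq = exon1 + intron + exon2
        gene = GeneModel("g", "c", "+", [(1, 9), (19, 27)], [(1, 9), (19, 27)])
        genome = {"c": seq}
        effect = analyze_gene(gene, genome, [("c", 10, "G", "C")])[0]
        assert not effect.stop_found
        assert effect.stop_offset_nt is None
        assert len(effect.truncated_protein) == (9 + 9 + 9) // 3


class TestRegionProfile:
    def test_fixed_difference_window_peaks_at_one(self):
        """HG-fixed alt, LG-fixed ref + neutral flanks: peak at the variant."""
        rng = np.random.default_rng(9)
        n_flank = 30
        flanks = (rng.random((n_flank, 40)) < 0.3).astype(np.int8)
        fixed = np.array([[1] * 20 + [0] * 20], dtype=np.int8)
        hap = np.vstack([flanks[:15], fixed, flanks[15:]])
        pos = np.concatenate(
            [
                np.linspace(1_000, 29_000, 15).astype(int),
                [30_000],
                np.linspace(31_000, 59_000, 15).astype(int),
            ]
        )
        m = matrix_from_haplotypes(hap, positions=pos, pops=["H1"] * 10 + ["L1"] * 10)
        prof = region_fst_profile(m, "Chr1", 0, 60_000, size=10_000, step=10_000)
        peak = prof.loc[prof["fst"].idxmax()]
        assert peak["start"] <= 30_000 - 1 < peak["end"]  # window holds the variant
        assert prof["fst"].max() > 2 * prof["fst"].median()

    def test_identical_groups_flat_near_zero(self):
        rng = np.random.default_rng(10)
        h = (rng.random((40, 20)) < 0.4).astype(np.int8)
        hap = np.hstack([h, h])
        pos = np.sort(rng.choice(np.arange(1, 40_001), 40, replace=False))
        m = matrix_from_haplotypes(hap, positions=pos, pops=["H1"] * 10 + ["L1"] * 10)
        prof = region_fst_profile(m, "Chr1", 0, 40_000, size=20_000, step=10_000)
        assert np.nanmax(np.abs(prof["fst"])) < 0.05

    def test_window_with_only_fixed_difference_is_one(self):
        hap = np.array([[1] * 10 + [0] * 10], dtype=np.int8)
        m = matrix_from_haplotypes(hap, positions=[5_000], pops=["H1"] * 5 + ["L1"] * 5)
        prof = region_fst_profile(m, "Chr1", 0, 10_000, size=10_000, step=10_000)
        assert prof["fst"].iloc[0] == pytest.approx(1.0)
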