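"""Diversity statistics against explicit pairwise-difference oracles."""

import numpy as np
import pytest

from pennyscan.diversity_stats import (
    SFSpectrum,
    compute_sfs,
    fold_sfs,
    make_windows,
    tajima_constants,
    window_diversity,
)

from conftest import matrix_from_haplotypes


def pairwise_pi_oracle(hap):
    """Mean pairwise difference summed over sites, by explicit double loop."""
    hap = np.asarray(hap)
    n = hap.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sum(hap[:, i] != hap[:, j])
    return total / (n * (n - 1) / 2)


class TestWindows:
    @pytest.mark.parametrize(
        "length,expected_n,last",
        [(100_000, 9, (80_000, 100_000)), (20_000, 1, (0, 20_000)), (19_999, 0, None)],
    )
    def test_window_arithmetic(self, length, expected_n, last):
        wins = make_windows({"c": length})
        assert len(wins) == expected_n
        if last:
            assert (wins[-1].start, wins[-1].end) == last

    def test_step_must_not_exceed_size(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100_000}, size=10_000, step=20_000)


class TestWindowDiversity:
    def test_single_site_doubleton_values(self):
        """4 haplotypes, one site at derived count 2: pi = 2/3, thetaW = 1/a1."""
        hap = np.array([[1, 1, 0, 0]])
        m = matrix_from_haplotypes(hap, positions=[1], pops=["H1", "H1"])
        wins = make_windows({"Chr1": 20_000})
        d = window_diversity(m, "H1", wins)
        L = 20_000
        assert d.loc[0, "theta_pi"] * L == pytest.approx(2 / 3, rel=1e-12)
        assert d.loc[0, "theta_pi"] * L == pytest.approx(pairwise_pi_oracle(hap), rel=1e-12)
        a1 = 1 + 1 / 2 + 1 / 3
        assert d.loc[0, "theta_w"] * L == pytest.approx(1 / a1, rel=1e-12)

    def test_theta_pi_equals_pairwise_oracle_on_random_matrices(self):
        """Formula-based pi equals explicit pair enumeration, 100 matrices."""
        rng = np.random.default_rng(123)
        wins = make_windows({"Chr1": 20_000})
        for _ in range(100):
            n_hap = 2 * int(rng.integers(2, 6))  # n <= 10 haplotypes
            n_sites = int(rng.integers(1, 51))
            hap = (rng.random((n_sites, n_hap)) < rng.uniform(0.1, 0.9)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 20_001), size=n_sites, replace=False))
            m = matrix_from_haplotypes(hap, positions=pos, pops=["H1"] * (n_hap // 2))
            d = window_diversity(m, "H1", wins)
            assert d.loc[0, "theta_pi"] * 20_000 == pytest.approx(
                pairwise_pi_oracle(hap), rel=1e-12, abs=1e-15
            )

    def test_engineered_window_gives_tajima_d_zero(self):
        """8 singletons + 3 doubletons at n=4: theta_pi = theta_w exactly."""
        rows = [[1, 0, 0, 0]] * 4 + [[0, 1, 0, 0]] * 4 + [[1, 1, 0, 0]] * 3
        m = matrix_from_haplotypes(np.array(rows), pops=["H1", "H1"])
        d = window_diversity(m, "H1", make_windows({"Chr1": 20_000}))
        assert d.loc[0, "tajima_d"] == pytest.approx(0.0, abs=1e-12)

    def test_singletons_negative_intermediates_positive(self):
        singles = matrix_from_haplotypes(
            np.eye(12, 8, dtype=np.int8), pops=["H1"] * 4
        )
        d_neg = window_diversity(singles, "H1", make_windows({"Chr1": 20_000}))
        inter = matrix_from_haplotypes(
            np.tile([1, 1, 1, 1, 0, 0, 0, 0], (12, 1)).astype(np.int8), pops=["H1"] * 4
        )
        d_pos = window_diversity(inter, "H1", make_windows({"Chr1": 20_000}))
        assert d_neg.loc[0, "tajima_d"] < 0 < d_pos.loc[0, "tajima_d"]

    def test_no_segregating_sites_gives_undefined_d(self):
        m = matrix_from_haplotypes(np.ones((3, 8), dtype=np.int8), pops=["H1"] * 4)
        d = window_diversity(m, "H1", make_windows({"Chr1": 20_000}))
        assert d.loc[0, "S"] == 0
        assert np.isnan(d.loc[0, "tajima_d"])

    def test_unknown_population_rejected(self, neutral_cohort):
        with pytest.raises(ValueError, match="no samples"):
            window_diversity(neutral_cohort, "NOPE", make_windows({"Chr1": 20_000}))

    def test_missing_genotypes_lower_site_n(self):
        hap = np.array([[1, 1, 0, 0]])
        m = matrix_from_haplotypes(hap, pops=["H1", "H1"])
        m.dosage[0, 0] = -1
        m.haplotypes = None
        d = window_diversity(m, "H1", make_windows({"Chr1": 20_000}))
        assert d.loc[0, "n_eff"] == 2.0  # one diploid left
        # p = 0 among remaining: site no longer segregating
        assert d.loc[0, "S"] == 0


class TestTajimaConstants:
    def test_known_values_n4(self):
        c = tajima_constants(4)
        assert c["a1"] == pytest.approx(11 / 6)
        assert c["b1"] == pytest.approx(5 / 9)


class TestSfs:
    def _matrix(self):
        # derived counts {1, 1, 2} in n = 4 haplotypes
        hap = np.array([[1, 0, 0, 0], [0, 0, 1, 0], [1, 1, 0, 0]])
        return matrix_from_haplotypes(hap, pops=["H1", "H1"])

    def test_unfolded_tally(self):
        sfs = compute_sfs(self._matrix(), population="H1", folded=False)
        assert sfs.counts.tolist() == [0, 2, 1, 0, 0]

    def test_folded_tally(self):
        sfs = compute_sfs(self._matrix(), population="H1", folded=True)
        assert sfs.counts.tolist() == [0, 2, 1]

    def test_folding_consistency(self, neutral_cohort):
        unfolded = compute_sfs(neutral_cohort, group="HG", folded=False)
        folded = compute_sfs(neutral_cohort, group="HG", folded=True)
        np.testing.assert_allclose(fold_sfs(unfolded).counts, folded.counts)

    def test_maf_boundary_kept(self):
        """A singleton at exactly maf_min survives the strict '<' exclusion."""
        hap = np.zeros((1, 20), dtype=np.int8)
        hap[0, 0] = 1  # freq 0.05 in n = 20
        m = matrix_from_haplotypes(hap, pops=["H1"] * 10)
        sfs = compute_sfs(m, population="H1", folded=False, maf_min=0.05)
        assert sfs.counts[1] == 1
        below = compute_sfs(m, population="H1", folded=False, maf_min=0.051)
        assert below.counts[1] == 0

    def test_unfolded_needs_ancestral_states(self):
        hap = np.array([[1, 0, 0, 0]])
        m = matrix_from_haplotypes(hap, pops=["H1", "H1"], anc=False)
        with pytest.raises(ValueError, match="ancestral"):
            compute_sfs(m, population="H1", folded=False)

    def test_projection_preserves_mass(self):
        hap = np.array([[1, 1, 0, 0], [1, 0, 0, 0]])
        m = matrix_from_haplotypes(hap, pops=["H1", "H1"])
        m.dosage[1, 0] = -1
        m.haplotypes = None
        sfs = compute_sfs(
            m, population="H1", folded=False, missing_policy="project", project_n=2
        )
        assert sfs.total == pytest.approx(2.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SFSpectrum(n=4, counts=np.array([0, -1, 0, 0, 0]), folded=False)
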