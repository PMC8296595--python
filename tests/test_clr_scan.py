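"""The sweep-spectrum transform against exhaustive enumeration, and scan
behaviour on null and swept data."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pennyscan.clr_scan import (
    SweepModel,
    background_sfs,
    clr_outliers,
    clr_scan,
    default_alpha_grid,
    downsample_phi,
    group_clr_scan,
    sweep_sfs_transform,
)
from pennyscan.synthetic_data import SimConfig, inject_sweep, simulate_neutral_cohort

from conftest import matrix_from_haplotypes


def transform_oracle(phi, n, p_e):
    """Brute force: every escape pattern x pre-sweep count x sweeper choice.

    phi is the background distribution over derived counts 1..n-1. Each of
    the n lineages escapes independently with probability p_e. The escapees
    plus (if any lineage was caught) one sweeping ancestor form a pre-sweep
    sample whose derived count k follows phi hypergeometrically downsampled;
    the sweeper is a uniformly random member of that sample and its allele
    is copied onto the caught lineages.
    """
    out = np.zeros(n + 1)
    for pattern in itertools.product([0, 1], repeat=n):  # 1 = escape
        B = sum(pattern)
        w_pattern = (p_e**B) * ((1 - p_e) ** (n - B))
        if B == n:
            for j in range(1, n):
                out[j] += w_pattern * phi[j - 1]
            continue
        m = B + 1
        for j in range(1, n):  # background count in the original n-sample
            for k in range(0, m + 1):  # count among the m pre-sweep lineages
                h = (
                    math.comb(j, k) * math.comb(n - j, m - k) / math.comb(n, m)
                )
                if h == 0.0:
                    continue
                w = w_pattern * phi[j - 1] * h
                # sweeper uniform among the m: derived with prob k/m
                if k > 0:
                    out[(k - 1) + (n - B)] += w * (k / m)
                if k < m:
                    out[k] += w * (1 - k / m)
    poly = out[1:n]
    return poly / poly.sum()


class TestSweepTransform:
    def test_worked_three_lineage_example(self):
        got = sweep_sfs_transform(np.array([2 / 3, 1 / 3]), 3, 0.5)
        np.testing.assert_allclose(got, [11 / 18, 7 / 18], atol=1e-12)

    def test_full_escape_is_identity(self):
        phi = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(sweep_sfs_transform(phi, 4, 1.0), phi, atol=1e-12)

    def test_n2_invariant_under_any_escape(self):
        np.testing.assert_allclose(
            sweep_sfs_transform(np.array([1.0]), 2, 0.3), [1.0], atol=1e-12
        )

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(n)
        for p_e in np.arange(0.1, 0.95, 0.1):
            phi = rng.dirichlet(np.ones(n - 1))
            got = sweep_sfs_transform(phi, n, float(p_e))
            want = transform_oracle(phi, n, float(p_e))
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_output_sums_to_one(self):
        rng = np.random.default_rng(0)
        for n in (5, 10, 20):
            phi = rng.dirichlet(np.ones(n - 1))
            for p_e in (1e-6, 0.01, 0.5, 0.999):
                assert sweep_sfs_transform(phi, n, p_e).sum() == pytest.approx(1.0)

    def test_downsampling_preserves_mass(self):
        rng = np.random.default_rng(1)
        n = 12
        phi = rng.dirichlet(np.ones(n - 1))
        for m in range(1, n + 1):
            assert downsample_phi(phi, n, m).sum() == pytest.approx(1.0, rel=1e-12)


class TestBackgroundSfs:
    def test_normalized_probability_vector(self, neutral_cohort):
        phi = background_sfs(neutral_cohort, group="HG")
        assert phi.sum() == pytest.approx(1.0)
        assert (phi >= 0).all() and len(phi) == 39  # classes 1..n-1 at n=40

    def test_panmictic_cohort_is_one_over_j_shaped(self):
        """1/j neutral expectation holds for one deme without selfing."""
        cfg = SimConfig(
            seed=19, demes=[("P1", "G1", 10)], selfing=0.0, chrom_length=500_000
        )
        phi = background_sfs(simulate_neutral_cohort(cfg), population="P1")
        assert phi[0] > phi[1] > phi[3] > phi[9]

    def test_n2_single_class(self):
        hap = np.array([[1, 0], [0, 1], [1, 0]])
        m = matrix_from_haplotypes(hap, pops=["H1"])
        assert background_sfs(m, population="H1").tolist() == [1.0]

    def test_no_polymorphism_is_an_error(self):
        m = matrix_from_haplotypes(np.ones((2, 4), np.int8), pops=["H1", "H1"])
        with pytest.raises(ValueError, match="polymorphic"):
            background_sfs(m, population="H1")


class TestScan:
    def test_null_data_gives_small_median_and_nonnegative_clr(self):
        rng = np.random.default_rng(8)
        n = 10
        phi = (1.0 / np.arange(1, n)) / np.sum(1.0 / np.arange(1, n))
        j = rng.choice(np.arange(1, n), size=800, p=phi)
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), size=800, replace=False))
        sites = pd.DataFrame({"pos": pos, "j": j})
        points = clr_scan(sites, SweepModel(), phi, n, chrom_length=1_000_000)
        assert (points["clr"] >= -1e-9).all()
        assert points["clr"].median() < np.quantile(points["clr"], 0.99)

    def test_empty_alpha_grid_rejected(self):
        with pytest.raises(ValueError):
            SweepModel(alpha_grid=np.array([]))

    def test_argmax_near_injected_sweep(self):
        hits = 0
        for seed in range(5):
            m = simulate_neutral_cohort(SimConfig(seed=200 + seed))
            swept = inject_sweep(m, 510_000, 1e3, 1e-8, "HG", seed=300 + seed)
            points, _, _ = group_clr_scan(swept, "HG", chrom_length=1_000_000)
            argmax = points.loc[points["clr"].idxmax(), "position"]
            hits += abs(argmax - 510_000) <= 10_000
        assert hits >= 4

    def test_alpha_grid_brackets_requested_escape_range(self):
        grid = default_alpha_grid()
        pe = 1.0 - np.exp(-grid[:-1] * 1e-8 * 20_000)
        assert pe[0] == pytest.approx(0.01, rel=1e-6)
        assert pe[-1] == pytest.approx(0.99, rel=1e-6)
        assert np.isinf(grid[-1])


class TestOutliers:
    def test_quantile_flags_about_one_percent(self):
        rng = np.random.default_rng(3)
        points = pd.DataFrame(
            {"position": np.arange(1, 1001) * 10_000, "clr": rng.exponential(1.0, 1000)}
        )
        cutoff, regions = clr_outliers(points, 0.99, 10_000)
        n_flagged = int((points["clr"] >= cutoff).sum())
        assert 5 <= n_flagged <= 20  # ~10 of 1000

    def test_all_equal_ties_flagged(self):
        points = pd.DataFrame({"position": np.arange(1, 201) * 10_000, "clr": 1.0})
        cutoff, regions = clr_outliers(points, 0.99, 10_000)
        assert len(regions) == 1  # every point ties at the cutoff and merges
        assert regions["start"].iloc[0] == 10_000

    def test_too_few_points_flags_nothing(self):
        points = pd.DataFrame({"position": np.arange(1, 50) * 10_000, "clr": 1.0})
        cutoff, regions = clr_outliers(points, 0.99, 10_000)
        assert len(regions) == 0

    def test_sweep_region_contains_argmax(self):
        m = simulate_neutral_cohort(SimConfig(seed=207))
        swept = inject_sweep(m, 510_000, 1e3, 1e-8, "HG", seed=307)
        points, _, _ = group_clr_scan(swept, "HG", chrom_length=1_000_000)
        cutoff, regions = clr_outliers(points, 0.99, 10_000)
        argmax = points.loc[points["clr"].idxmax(), "position"]
        assert any(s <= argmax <= e for s, e in zip(regions["start"], regions["end"]))
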