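"""SweepFinder-style composite likelihood ratio sweep scan.

The test compares, at each grid position, the composite likelihood of the
observed derived-allele counts under a sweep-distorted site-frequency
spectrum against the genome-wide background spectrum. The sweep model is the
star-genealogy escape model: at distance d from the swept site each lineage
escapes the sweep with probability p_e = 1 - exp(-alpha * r_rec * d); the B
escapees plus one sweeping lineage form a pre-sweep sample of size B+1 whose
derived count is drawn from the background spectrum by hypergeometric
downsampling, and the sweeping lineage's allele is copied onto the n-B
non-escaped lineages. Counts are conditioned on polymorphism (classes
1..n-1), matching the original SweepFinder's polymorphic-only likelihood.

The alpha grid always includes an infinite value (p_e = 1 everywhere, the
neutral limit), so the neutral model is nested and CLR >= 0 exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from pennyscan.diversity_stats import SFSpectrum, compute_sfs
from pennyscan.io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


def default_alpha_grid(
    r_rec: float = 1e-8,
    d_ref: float = 20_000.0,
    pe_lo: float = 0.01,
    pe_hi: float = 0.99,
    size: int = 20,
) -> np.ndarray:
    """Log-spaced alpha values bracketing escape probabilities at d_ref.

    Spans alphas for which p_e(d_ref) runs from ``pe_lo`` (strong, wide
    sweep) to ``pe_hi`` (nearly neutral); an infinite alpha (exact
    neutrality) is appended.
    """
    a_lo = -math.log(1.0 - pe_lo) / (r_rec * d_ref)
    a_hi = -math.log(1.0 - pe_hi) / (r_rec * d_ref)
    grid = np.geomspace(a_lo, a_hi, size)
    return np.append(grid, np.inf)


@dataclass
class SweepModel:
    """Scan settings: test grid, alpha grid, recombination scale."""

    r_rec: float = 1e-8
    alpha_grid: np.ndarray = field(default_factory=lambda: default_alpha_grid())
    grid_step: int = 10_000
    radius: int = 200_000
    escape_floor: float = 1e-6
    pe_grid_size: int = 1001

    def __post_init__(self) -> None:
        self.alpha_grid = np.sort(np.asarray(self.alpha_grid, dtype=float))
        if self.alpha_grid.size == 0:
            raise ValueError("empty alpha grid")
        if np.any(self.alpha_grid <= 0):
            raise ValueError("alpha values must be > 0")


def background_sfs(matrix: GenotypeMatrix, group: str | None = None,
                   population: str | None = None) -> np.ndarray:
    """Normalized unfolded background spectrum over classes 1..n-1.

    Returns phi as a length n-1 probability vector (index 0 = derived count
    1). Sites with missing genotypes are dropped.
    """
    sfs: SFSpectrum = compute_sfs(
        matrix, population=population, group=group, folded=False,
        missing_policy="drop", polymorphic_only=True,
    )
    phi = np.asarray(sfs.counts[1:-1], dtype=float)
    total = phi.sum()
    if total <= 0:
        raise ValueError("no polymorphic sites: background SFS undefined")
    return phi / total


def downsample_phi(phi: np.ndarray, n: int, m: int) -> np.ndarray:
    """Distribution of the derived count in a subsample of size m <= n.

    ``phi`` is the polymorphic spectrum over derived counts 1..n-1 in a
    sample of n; the result is over 0..m (monomorphic subsamples allowed),
    with total mass preserved.
    """
    if m > n:
        raise ValueError("cannot downsample to a larger sample")
    j = np.arange(1, n)
    k = np.arange(0, m + 1)
    # pmf matrix: rows k, cols j
    pm = hypergeom.pmf(k[:, None], n, j[None, :], m)
    return pm @ phi


def _star_kernels(phi: np.ndarray, n: int) -> np.ndarray:
    """G[B, f]: distribution of the final derived count given B escapees.

    Independent of p_e; the transform for any escape probability is the
    binomial mixture over B of these kernels.
    """
    G = np.zeros((n + 1, n + 1))
    for B in range(n):
        m = B + 1
        phi_m = downsample_phi(phi, n, m)  # over k = 0..m
        for k in range(m + 1):
            w = phi_m[k]
            if w == 0.0:
                continue
            pr_derived = k / m
            if pr_derived > 0:
                G[B, (k - 1) + (n - B)] += w * pr_derived
            G[B, k] += w * (1.0 - pr_derived)
    G[n, 1:n] = phi  # all lineages escape: background unchanged
    return G


def sweep_sfs_transform(phi: np.ndarray, n: int, p_e: float,
                        escape_floor: float = 1e-6) -> np.ndarray:
    """Sweep-distorted spectrum over derived counts 1..n-1 at escape prob p_e.

    Exact computation (full mixture over escapee counts); conditioned on
    polymorphism and renormalized. p_e is floored at ``escape_floor``.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (n - 1,):
        raise ValueError("phi must have length n-1")
    p_e = max(float(p_e), escape_floor)
    if p_e > 1.0:
        raise ValueError("p_e must be <= 1")
    G = _star_kernels(phi, n)
    weights = binom.pmf(np.arange(n + 1), n, p_e)
    full = weights @ G
    poly = full[1:n]
    total = poly.sum()
    if total <= 0:
        raise ValueError("degenerate sweep model: no polymorphic mass")
    return poly / total


@dataclass
class CLRPoint:
    position: int
    clr: float
    alpha_hat: float


def _transform_table(phi: np.ndarray, n: int, model: SweepModel) -> tuple[np.ndarray, np.ndarray]:
    """Log sweep-spectrum table over a p_e grid; (pe_grid, log_table).

    Row i holds log probabilities of classes 1..n-1 at pe_grid[i]; the first
    grid value is the escape floor rather than 0 (p_e = 0 is degenerate).
    """
    pe_grid = np.linspace(0.0, 1.0, model.pe_grid_size)
    pe_grid[0] = model.escape_floor
    G = _star_kernels(phi, n)
    B = np.arange(n + 1)
    weights = binom.pmf(B[None, :], n, pe_grid[:, None])  # (n_pe, n+1)
    full = weights @ G
    poly = full[:, 1:n]
    poly /= poly.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        return pe_grid, np.log(poly)


def clr_scan(
    sites: pd.DataFrame,
    model: SweepModel,
    phi: np.ndarray,
    n: int,
    grid_positions: np.ndarray | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Composite likelihood ratio at each grid position.

    ``sites`` needs columns pos (1-based) and j (derived count, 1..n-1);
    a column n may give per-site haploid sample sizes (defaults to ``n``);
    sites whose sample size differs from ``n`` are handled by downsampling
    the background to that size. Sites farther than ``model.radius`` from a
    grid position enter neither likelihood at that position.

    Returns a DataFrame with position, clr and alpha_hat.
    """
    if model.alpha_grid.size == 0:
        raise ValueError("empty alpha grid")
    pos = sites["pos"].to_numpy(dtype=float)
    j = sites["j"].to_numpy(dtype=int)
    n_i = sites["n"].to_numpy(dtype=int) if "n" in sites.columns else np.full(j.size, n)
    order = np.argsort(pos, kind="stable")
    pos, j, n_i = pos[order], j[order], n_i[order]
    keep = (j >= 1) & (j <= n_i - 1)
    pos, j, n_i = pos[keep], j[keep], n_i[keep]

    if grid_positions is None:
        hi = int(chrom_length if chrom_length is not None else pos.max())
        grid_positions = np.arange(model.grid_step, hi + 1, model.grid_step)

    # per-distinct-n structures
    tables: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for nn in np.unique(n_i):
        if nn == n:
            phi_n = phi
        else:
            sub = downsample_phi(phi, n, int(nn))[1:nn]
            phi_n = sub / sub.sum()
        pe_grid, log_table = _transform_table(phi_n, int(nn), model)
        with np.errstate(divide="ignore"):
            log_phi = np.log(phi_n)
        tables[int(nn)] = (pe_grid, log_table, log_phi)

    n_pe = model.pe_grid_size
    rows = []
    finite_alpha = model.alpha_grid[np.isfinite(model.alpha_grid)]
    for x in grid_positions:
        lo = np.searchsorted(pos, x - model.radius)
        hi_i = np.searchsorted(pos, x + model.radius, side="right")
        if hi_i <= lo:
            rows.append((int(x), 0.0, np.inf))
            continue
        d = np.abs(pos[lo:hi_i] - x)
        jj = j[lo:hi_i]
        nn_slice = n_i[lo:hi_i]
        l_neutral = 0.0
        best = -np.inf
        best_alpha = np.inf
        for nn in np.unique(nn_slice):
            _, _, log_phi = tables[int(nn)]
            sel = nn_slice == nn
            l_neutral += log_phi[jj[sel] - 1].sum()
        for alpha in model.alpha_grid:
            l_sweep = 0.0
            for nn in np.unique(nn_slice):
                pe_grid, log_table, _ = tables[int(nn)]
                sel = nn_slice == nn
                if np.isinf(alpha):
                    pe_idx = np.full(int(sel.sum()), n_pe - 1)
                else:
                    pe = 1.0 - np.exp(-alpha * model.r_rec * d[sel])
                    pe = np.maximum(pe, model.escape_floor)
                    pe_idx = np.rint(pe * (n_pe - 1)).astype(int)
                l_sweep += log_table[pe_idx, jj[sel] - 1].sum()
            if l_sweep > best:
                best = l_sweep
                best_alpha = alpha
        rows.append((int(x), 2.0 * (best - l_neutral), best_alpha))
    return pd.DataFrame(rows, columns=["position", "clr", "alpha_hat"])


def clr_outliers(
    points: pd.DataFrame,
    quantile: float = 0.99,
    grid_step: int | None = None,
    min_points: int = 100,
) -> tuple[float, pd.DataFrame]:
    """Top-quantile CLR outlier positions merged into regions.

    Returns (cutoff, regions DataFrame with chrom-free start/end in bp,
    1-based inclusive position bounds plus 0-based half-open bed_start/
    bed_end). Positions >= the empirical quantile are outliers; flagged
    positions within one grid step merge. Each grid position represents its
    surrounding half-step cell, so region bounds extend grid_step/2 beyond
    the outer flagged positions. With fewer than ``min_points`` grid points
    no position is flagged (warning logged).
    """
    clr = points["clr"].to_numpy(dtype=float)
    pos = points["position"].to_numpy(dtype=int)
    if clr.size == 0:
        raise ValueError("no CLR points")
    if clr.size < min_points:
        logger.warning("only %d CLR points; quantile threshold unreliable, none flagged", clr.size)
        return float("inf"), pd.DataFrame(columns=["start", "end", "bed_start", "bed_end", "max_clr"])
    cutoff = float(np.quantile(clr, quantile))
    if grid_step is None:
        grid_step = int(np.min(np.diff(np.sort(pos)))) if pos.size > 1 else 1
    flagged = np.sort(pos[clr >= cutoff])
    regions = []
    if flagged.size:
        start = prev = flagged[0]
        for p in flagged[1:]:
            if p - prev <= grid_step:
                prev = p
            else:
                regions.append((start, prev))
                start = prev = p
        regions.append((start, prev))
    out = pd.DataFrame(regions, columns=["start", "end"])
    if len(out):
        by_pos = dict(zip(pos, clr))
        half = grid_step // 2
        out["bed_start"] = np.maximum(out["start"] - 1 - half, 0)
        out["bed_end"] = out["end"] + half
        out["max_clr"] = [
            max(by_pos[p] for p in pos if s <= p <= e) for s, e in zip(out["start"], out["end"])
        ]
    else:
        out["bed_start"] = out["bed_end"] = out["max_clr"] = []
    return cutoff, out


def group_clr_scan(
    matrix: GenotypeMatrix,
    group: str,
    model: SweepModel | None = None,
    chrom_length: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Convenience: background SFS + scan for one group of a cohort.

    Uses complete sites only (no missing genotypes within the group) so the
    per-site sample size is constant. Returns (points, phi, n).
    """
    from pennyscan.diversity_stats import allele_counts

    model = model or SweepModel()
    counts = allele_counts(matrix, group=group)
    if "dac" not in counts.columns:
        raise ValueError("CLR scan requires ancestral-state annotations")
    n = int(counts["n"].max())
    ok = (counts["n"] == n) & counts["dac"].notna()
    phi = background_sfs(matrix, group=group)
    seg = ok & (counts["dac"] >= 1) & (counts["dac"] <= n - 1)
    sites = pd.DataFrame(
        {"pos": counts.loc[seg, "pos"], "j": counts.loc[seg, "dac"].astype(int)}
    )
    points = clr_scan(sites, model, phi, n, chrom_length=chrom_length)
    return points, phi, n
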