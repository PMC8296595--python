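"""Pairwise and composite F_ST scans over the 2-high x 2-low design.

Window F_ST is the Hudson estimator formed as a ratio of averages: per-site
numerator and denominator components are summed over the window and divided
once (robust for 20-kb windows with ~10 diploids per population). The
four-pair composite is the root mean square of the window F_ST values of
(H1,L1), (H1,L2), (H2,L1), (H2,L2); negative window values are clamped to 0
before squaring. The theta_pi ratio compares pooled-group diversity between
the two elevation groups.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from pennyscan.diversity_stats import WindowSpec, _window_site_slices, allele_counts, window_diversity
from pennyscan.io_formats import GenotypeMatrix


def hudson_fst_components(
    p1: float, n1: float, p2: float, n2: float
) -> tuple[float, float]:
    """Per-site Hudson F_ST numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    n1, n2 are haploid sample sizes (must exceed 1).
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("need at least 2 haploid genomes per deme")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _pair_window_fst(
    matrix: GenotypeMatrix,
    windows: list[WindowSpec],
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    clamp: bool = True,
) -> np.ndarray:
    """Window-level ratio-of-averages Hudson F_ST for one deme pair."""
    ac_a, n_a = counts_a["ac"].to_numpy(float), counts_a["n"].to_numpy(float)
    ac_b, n_b = counts_b["ac"].to_numpy(float), counts_b["n"].to_numpy(float)
    ok = (n_a > 1) & (n_b > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n_a > 0, ac_a / n_a, 0.0)
        p2 = np.where(n_b > 0, ac_b / n_b, 0.0)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n_a - 1, 1) - p2 * (
            1 - p2
        ) / np.maximum(n_b - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)

    out = np.full(len(windows), np.nan)
    for wi, (w, idx) in enumerate(_window_site_slices(matrix.sites, windows)):
        if idx.size == 0:
            continue
        dsum = den[idx].sum()
        if dsum <= 0:
            continue
        fst = num[idx].sum() / dsum
        if clamp:
            fst = min(1.0, max(0.0, fst))
        out[wi] = fst
    return out


def pairwise_window_fst(
    matrix: GenotypeMatrix,
    windows: list[WindowSpec],
    populations: list[str] | None = None,
    clamp: bool = True,
) -> pd.DataFrame:
    """Window F_ST for every population pair; columns ``fst_<A>_<B>``."""
    pops = populations or list(dict.fromkeys(matrix.populations))
    counts = {p: allele_counts(matrix, population=p) for p in pops}
    out = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )
    for a, b in itertools.combinations(pops, 2):
        out[f"fst_{a}_{b}"] = _pair_window_fst(matrix, windows, counts[a], counts[b], clamp)
    return out


def fst_rms(f_h1l1: float, f_h1l2: float, f_h2l1: float, f_h2l2: float) -> float:
    """Root mean square of the four high-vs-low pairwise window F_ST values.

    Returns NaN when any input is missing. Inputs are clamped at 0.
    """
    vals = [f_h1l1, f_h1l2, f_h2l1, f_h2l2]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return float("nan")
    vals = [max(0.0, float(v)) for v in vals]
    return math.sqrt(sum(v * v for v in vals) / 4.0)


def pi_ratio(theta_pi_num: float, theta_pi_den: float, pseudocount: float = 1e-8) -> float:
    """(theta_pi_num + eps) / (theta_pi_den + eps)."""
    return (theta_pi_num + pseudocount) / (theta_pi_den + pseudocount)


def group_fst_profile(
    matrix: GenotypeMatrix,
    windows: list[WindowSpec],
    group_a: str = "HG",
    group_b: str = "LG",
    clamp: bool = True,
) -> pd.DataFrame:
    """Per-window Hudson F_ST with each group pooled as a single deme."""
    counts_a = allele_counts(matrix, group=group_a)
    counts_b = allele_counts(matrix, group=group_b)
    fst = _pair_window_fst(matrix, windows, counts_a, counts_b, clamp)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "fst": fst,
        }
    )


def composite_scan(
    matrix: GenotypeMatrix,
    windows: list[WindowSpec],
    high_pops: list[str],
    low_pops: list[str],
    high_group: str = "HG",
    low_group: str = "LG",
    pseudocount: float = 1e-8,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Per-window F_ST(rms), pooled-group theta_pi and both pi ratios.

    Windows with fewer than ``min_snps`` segregating sites in either pooled
    group are masked (statistics set to NaN) to avoid unstable ratios;
    the ``masked`` column records which.
    """
    if len(high_pops) != 2 or len(low_pops) != 2:
        raise ValueError("composite scan expects exactly 2 high and 2 low populations")
    pair_fst = pairwise_window_fst(matrix, windows, populations=high_pops + low_pops)
    div_h = window_diversity(matrix, population=None, group=high_group, windows=windows)
    div_l = window_diversity(matrix, population=None, group=low_group, windows=windows)

    h1, h2 = high_pops
    l1, l2 = low_pops

    def col(a: str, b: str) -> np.ndarray:
        name = f"fst_{a}_{b}" if f"fst_{a}_{b}" in pair_fst.columns else f"fst_{b}_{a}"
        return pair_fst[name].to_numpy()

    rms = np.array(
        [
            fst_rms(x1, x2, x3, x4)
            for x1, x2, x3, x4 in zip(col(h1, l1), col(h1, l2), col(h2, l1), col(h2, l2))
        ]
    )
    pi_h = div_h["theta_pi"].to_numpy()
    pi_l = div_l["theta_pi"].to_numpy()
    ratio_hg = np.array([pi_ratio(l, h, pseudocount) for l, h in zip(pi_l, pi_h)])
    ratio_lg = np.array([pi_ratio(h, l, pseudocount) for h, l in zip(pi_h, pi_l)])

    masked = (div_h["S"].to_numpy() < min_snps) | (div_l["S"].to_numpy() < min_snps)
    out = pair_fst.copy()
    out["theta_pi_HG"] = pi_h
    out["theta_pi_LG"] = pi_l
    out["fst_rms"] = np.where(masked, np.nan, rms)
    out["pi_ratio_HG"] = np.where(masked, np.nan, ratio_hg)
    out["pi_ratio_LG"] = np.where(masked, np.nan, ratio_lg)
    out["masked"] = masked
    return out
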