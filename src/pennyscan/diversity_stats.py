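"""Windowed diversity statistics and site-frequency spectra.

Windows are 20 kb with a 50%-overlapping 10-kb step by default, 0-based
half-open, dropped (not truncated) at chromosome ends so per-bp values stay
comparable. theta_pi uses the unbiased per-site heterozygosity
2*p*(1-p)*n/(n-1) with n the site's non-missing haploid count; Watterson's
theta and Tajima's D use the window's rounded mean n, with the 1989 variance
constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from pennyscan.io_formats import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    chrom: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SFSpectrum:
    """Site-frequency counts at haploid sample size n.

    Unfolded: counts indexed by derived-allele count 0..n. Folded: by
    minor-allele count 0..floor(n/2). Counts may be fractional when sites
    with missing data are hypergeometrically projected down.
    """

    n: int
    counts: np.ndarray
    folded: bool
    polymorphic_only: bool = False

    def __post_init__(self) -> None:
        expect = self.n // 2 + 1 if self.folded else self.n + 1
        if len(self.counts) != expect:
            raise ValueError("counts length does not match sample size")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("negative SFS counts")

    @property
    def total(self) -> float:
        return float(np.sum(self.counts))


def make_windows(
    chrom_lengths: Mapping[str, int], size: int = 20_000, step: int = 10_000
) -> list[WindowSpec]:
    """Sliding windows starting at 0; windows past the chromosome end dropped."""
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be > 0")
    if step > size:
        raise ValueError("step must be <= size")
    out = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start + size <= length:
            out.append(WindowSpec(chrom, start, start + size))
            start += step
    return out


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's 1989 variance constants for haploid sample size n >= 2."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def allele_counts(
    matrix: GenotypeMatrix,
    population: str | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-site alt counts within a population or group.

    Returns a DataFrame with chrom, pos, ac (alt-allele count over non-missing
    haploid genomes), n (non-missing haploid count), and, when ancestral
    states are available, derived count ``dac`` (NaN where the ancestral
    allele matches neither ref nor alt).
    """
    idx = matrix.sample_indices(population=population, group=group)
    dos = matrix.dosage[:, idx]
    missing = dos == MISSING
    n = 2 * (dos.shape[1] - missing.sum(axis=1))
    ac = np.where(missing, 0, dos).sum(axis=1)
    out = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"].to_numpy(),
            "pos": matrix.sites["pos"].to_numpy(),
            "ac": ac.astype(int),
            "n": n.astype(int),
        }
    )
    if "anc" in matrix.sites.columns and matrix.sites["anc"].notna().any():
        anc = matrix.sites["anc"].to_numpy()
        ref = matrix.sites["ref"].to_numpy()
        alt = matrix.sites["alt"].to_numpy()
        dac = np.where(anc == ref, ac, np.where(anc == alt, n - ac, np.nan))
        out["dac"] = dac
    return out


def _window_site_slices(sites: pd.DataFrame, windows: list[WindowSpec]):
    """Yield (window, index array of sites inside it), via per-chrom bisection."""
    by_chrom = {
        chrom: (sub.index.to_numpy(), sub["pos"].to_numpy())
        for chrom, sub in sites.groupby("chrom", sort=False)
    }
    for w in windows:
        if w.chrom not in by_chrom:
            yield w, np.array([], dtype=int)
            continue
        idx, pos = by_chrom[w.chrom]
        # pos is 1-based; window [start, end) 0-based half-open
        lo = np.searchsorted(pos, w.start + 1, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        yield w, idx[lo:hi]


def window_diversity(
    matrix: GenotypeMatrix,
    population: str | None,
    windows: list[WindowSpec],
    group: str | None = None,
) -> pd.DataFrame:
    """Per-window S, theta_pi, theta_w (per bp) and Tajima's D.

    Sites with fewer than 2 non-missing haploid genomes are not counted.
    Tajima's D is NaN when S = 0. ``n_eff`` reports the window's mean
    non-missing haploid sample size over counted sites.
    """
    counts = allele_counts(matrix, population=population, group=group)
    usable = counts["n"].to_numpy() >= 2
    ac = counts["ac"].to_numpy().astype(float)
    n = counts["n"].to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, ac / n, 0.0)
        het = np.where(usable, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1.0), 0.0)
    seg = usable & (ac > 0) & (ac < n)

    rows = []
    for w, idx in _window_site_slices(matrix.sites, windows):
        idx = idx[usable[idx]] if idx.size else idx
        S = int(seg[idx].sum()) if idx.size else 0
        pi_total = float(het[idx].sum()) if idx.size else 0.0
        n_mean = float(n[idx].mean()) if idx.size else 2.0 * matrix.sample_indices(
            population=population, group=group
        ).size
        n_round = max(2, int(round(n_mean)))
        theta_pi = pi_total / w.length
        if S > 0:
            const = tajima_constants(n_round)
            theta_w_total = S / const["a1"]
            var = const["e1"] * S + const["e2"] * S * (S - 1)
            D = (pi_total - theta_w_total) / np.sqrt(var) if var > 0 else np.nan
            theta_w = theta_w_total / w.length
        else:
            theta_w, D = 0.0, np.nan
        rows.append(
            (w.chrom, w.start, w.end, population or group, S, theta_pi, theta_w, D, n_mean)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "pop", "S",
            "theta_pi", "theta_w", "tajima_d", "n_eff",
        ],
    )


def fold_sfs(sfs: SFSpectrum) -> SFSpectrum:
    """Fold an unfolded spectrum: class j maps to min(j, n - j)."""
    if sfs.folded:
        return sfs
    n = sfs.n
    counts = np.zeros(n // 2 + 1)
    for j in range(n + 1):
        counts[min(j, n - j)] += sfs.counts[j]
    return SFSpectrum(n=n, counts=counts, folded=True, polymorphic_only=sfs.polymorphic_only)


def compute_sfs(
    matrix: GenotypeMatrix,
    population: str | None = None,
    group: str | None = None,
    folded: bool = False,
    maf_min: float = 0.0,
    missing_policy: str = "drop",
    project_n: int | None = None,
    polymorphic_only: bool = False,
) -> SFSpectrum:
    """Site-frequency spectrum for one population or group.

    Unfolded spectra require ancestral annotations (``anc`` site column);
    sites whose ancestral allele matches neither ref nor alt are dropped.
    Sites with missing genotypes are either dropped (``missing_policy=
    'drop'``) or projected down to ``project_n`` haploid genomes by
    hypergeometric downsampling (fractional counts). Sites with minor allele
    frequency strictly below ``maf_min`` are excluded (the boundary is kept).
    """
    counts = allele_counts(matrix, population=population, group=group)
    n_full = 2 * matrix.sample_indices(population=population, group=group).size
    if not folded:
        if "dac" not in counts.columns:
            raise ValueError("unfolded SFS requires ancestral-state annotations")
        counts = counts[counts["dac"].notna()]
        j = counts["dac"].to_numpy().astype(float)
    else:
        j = counts["ac"].to_numpy().astype(float)
    n = counts["n"].to_numpy().astype(float)

    keep = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, j / n, 0.0)
        maf = np.minimum(freq, 1.0 - freq)
    if maf_min > 0:
        keep &= maf >= maf_min  # strict "< maf_min" excluded
    j, n = j[keep], n[keep]

    target_n = project_n if (missing_policy == "project" and project_n) else n_full
    spectrum = np.zeros(target_n + 1)
    complete = n == target_n
    np.add.at(spectrum, j[complete].astype(int), 1.0)
    incomplete = ~complete
    if np.any(incomplete):
        if missing_policy == "drop":
            pass
        elif missing_policy == "project":
            for ji, ni in zip(j[incomplete], n[incomplete]):
                if ni < target_n:
                    continue
                k = np.arange(target_n + 1)
                spectrum += hypergeom.pmf(k, int(ni), int(ji), target_n)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

    sfs = SFSpectrum(n=target_n, counts=spectrum, folded=False)
    if polymorphic_only:
        sfs.counts[0] = 0.0
        sfs.counts[target_n] = 0.0
        sfs.polymorphic_only = True
    if folded:
        sfs = fold_sfs(sfs)
    return sfs


def write_sfs(path, sfs: SFSpectrum) -> None:
    """Two-column TSV: allele-count class, site count."""
    with open(path, "w") as fh:
        label = "minor_count" if sfs.folded else "derived_count"
        fh.write(f"{label}\tn_sites\n")
        for k, c in enumerate(sfs.counts):
            fh.write(f"{k}\t{c:g}\n")
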