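"""Linkage disequilibrium decay: pairwise r² against physical distance.

Two estimators: haplotype mode computes the classical
r² = D²/(p_A p_a p_B p_b) from phased two-locus haplotype frequencies;
genotype mode uses the squared Pearson correlation of diploid dosage
vectors, the usual choice for unphased resequencing data. In the complete
selfing limit (all genotypes homozygous) the two coincide.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pennyscan.io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def pair_r2(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    mode: str = "haplotype",
) -> float:
    """r² between two sites from aligned allele (or dosage) vectors.

    Haplotype mode expects binary haplotype vectors; genotype mode expects
    dosage vectors (missing entries -1 are excluded pairwise). Returns NaN
    when either site is monomorphic over the retained entries.
    """
    a = np.asarray(alleles_a, dtype=float)
    b = np.asarray(alleles_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    if mode == "haplotype":
        pa = a.mean()
        pb = b.mean()
        pab = np.mean(a * b)
        D = pab - pa * pb
        denom = pa * (1 - pa) * pb * (1 - pb)
        return float(D * D / denom)
    if mode == "genotype":
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    raise ValueError(f"unknown mode {mode!r}")


def decay_curve(
    matrix: GenotypeMatrix,
    group: str | None = None,
    population: str | None = None,
    max_dist: int = 300_000,
    n_bins: int = 100,
    maf_min: float = 0.05,
    mode: str = "haplotype",
) -> pd.DataFrame:
    """Binned mean r² against pairwise distance for one group/population.

    All intra-chromosome site pairs separated by <= ``max_dist`` enter;
    sites with minor allele frequency < ``maf_min`` in the chosen samples
    are excluded first. Bin edges are linear. Returns a DataFrame with
    bin_start, bin_end, mean_r2 and n_pairs (bins with no pairs dropped).
    """
    idx = matrix.sample_indices(population=population, group=group)
    if mode == "haplotype":
        if matrix.haplotypes is None:
            raise ValueError("haplotype mode requires phased haplotypes")
        data = matrix.haplotypes[:, matrix.haplotype_columns(idx)].astype(float)
    else:
        data = matrix.dosage[:, idx].astype(float)
        data[data == MISSING] = np.nan

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(data, axis=1) / (1.0 if mode == "haplotype" else 2.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.isfinite(maf) & (maf >= maf_min) & (maf > 0)

    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    for chrom, sub in matrix.sites.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        rows = rows[keep[rows]]
        if rows.size < 2:
            continue
        pos = matrix.sites["pos"].to_numpy()[rows].astype(float)
        X = data[rows]
        # center rows ignoring NaN; complete-data fast path
        if not np.isnan(X).any():
            Xc = X - X.mean(axis=1, keepdims=True)
            norms = np.sqrt((Xc**2).sum(axis=1))
            for i in range(rows.size - 1):
                hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
                if hi <= i + 1:
                    continue
                d = pos[i + 1 : hi] - pos[i]
                r = (Xc[i + 1 : hi] @ Xc[i]) / (norms[i + 1 : hi] * norms[i])
                r2 = r * r
                b = np.minimum((d / max_dist * n_bins).astype(int), n_bins - 1)
                np.add.at(sums, b, r2)
                np.add.at(counts, b, 1)
        else:
            for i in range(rows.size - 1):
                hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
                for k in range(i + 1, hi):
                    r2 = pair_r2(
                        np.nan_to_num(X[i], nan=MISSING),
                        np.nan_to_num(X[k], nan=MISSING),
                        mode="genotype" if mode == "genotype" else "haplotype",
                    )
                    if np.isnan(r2):
                        continue
                    d = pos[k] - pos[i]
                    b = min(int(d / max_dist * n_bins), n_bins - 1)
                    sums[b] += r2
                    counts[b] += 1

    if counts.sum() == 0:
        logger.warning("LD decay: no qualifying site pairs")
    mask = counts > 0
    return pd.DataFrame(
        {
            "bin_start": edges[:-1][mask].astype(int),
            "bin_end": edges[1:][mask].astype(int),
            "mean_r2": np.where(counts[mask] > 0, sums[mask] / np.maximum(counts[mask], 1), np.nan),
            "n_pairs": counts[mask],
        }
    )
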