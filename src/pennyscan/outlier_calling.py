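"""Joint outlier identification and gene assignment.

The scan's terminal logic: windows in the top quantile of both F_ST(rms)
and the group's theta_pi ratio are joint outliers; merged joint regions
intersected with CLR outlier regions yield three-evidence selection calls;
genes overlapping a call by >= 1 bp become candidate positively selected
genes (PSGs). Ties at the cutoff are kept (outlier means value >= cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pennyscan.io_formats import GeneModel


def quantile_threshold(values: np.ndarray, q: float) -> float:
    """Empirical quantile (linear interpolation) over finite values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values for quantile threshold")
    return float(np.quantile(vals, q))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended 0-based half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Members of ``a`` that overlap any member of ``b`` by >= 1 bp."""
    b = merge_intervals(b)
    out = []
    for s, e in a:
        if any(s < be and bs < e for bs, be in b):
            out.append((s, e))
    return out


@dataclass
class SelectionCall:
    chrom: str
    start: int  # 0-based half-open
    end: int
    focal_group: str
    flags: dict[str, bool] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)


def joint_outliers(
    composite: pd.DataFrame,
    group: str = "HG",
    q: float = 0.97,
) -> pd.DataFrame:
    """Windows in the top (1-q) of both fst_rms and the group's pi ratio.

    ``composite`` is the output of ``differentiation.composite_scan``. The
    HG scan uses pi_ratio_HG = theta_pi(LG)/theta_pi(HG) (reduced focal
    diversity inflates the ratio); LG the reciprocal. Masked windows never
    qualify. Adds boolean columns fst_rms_top, pi_ratio_top, joint.
    """
    ratio_col = f"pi_ratio_{group}"
    if ratio_col not in composite.columns:
        raise ValueError(f"composite scan lacks column {ratio_col}")
    out = composite.copy()
    fst_cut = quantile_threshold(out["fst_rms"].to_numpy(), q)
    ratio_cut = quantile_threshold(out[ratio_col].to_numpy(), q)
    fst_top = out["fst_rms"].to_numpy() >= fst_cut
    ratio_top = out[ratio_col].to_numpy() >= ratio_cut
    valid = np.isfinite(out["fst_rms"].to_numpy()) & np.isfinite(out[ratio_col].to_numpy())
    out["fst_rms_top"] = fst_top & valid
    out["pi_ratio_top"] = ratio_top & valid
    out["joint"] = out["fst_rms_top"] & out["pi_ratio_top"]
    out.attrs["fst_rms_cutoff"] = fst_cut
    out.attrs["pi_ratio_cutoff"] = ratio_cut
    return out


def intersect_evidence(
    joint_windows: pd.DataFrame,
    clr_regions: pd.DataFrame,
    group: str = "HG",
) -> list[SelectionCall]:
    """Three-evidence calls: merged joint windows overlapping a CLR region.

    ``joint_windows`` is the output of ``joint_outliers`` (windows with the
    ``joint`` flag are merged, overlap-or-book-ended); ``clr_regions`` is the
    region table from ``clr_scan.clr_outliers`` (bed_start/bed_end columns).
    Intersection is region-level, >= 1 bp.
    """
    calls: list[SelectionCall] = []
    clr_iv = [
        (int(s), int(e))
        for s, e in zip(clr_regions.get("bed_start", []), clr_regions.get("bed_end", []))
    ]
    for chrom, sub in joint_windows[joint_windows["joint"]].groupby("chrom", sort=False):
        merged = merge_intervals(
            [(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        )
        hits = intersect_intervals(merged, clr_iv)
        for s, e in hits:
            calls.append(
                SelectionCall(
                    chrom=chrom,
                    start=s,
                    end=e,
                    focal_group=group,
                    flags={"fst_rms_top3": True, "pi_ratio_top3": True, "clr_top1": True},
                )
            )
    return calls


def joint_region_calls(joint_windows: pd.DataFrame, group: str = "HG") -> list[SelectionCall]:
    """Two-evidence calls (joint windows merged, no CLR requirement)."""
    calls = []
    for chrom, sub in joint_windows[joint_windows["joint"]].groupby("chrom", sort=False):
        for s, e in merge_intervals(
            [(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        ):
            calls.append(
                SelectionCall(
                    chrom=chrom, start=s, end=e, focal_group=group,
                    flags={"fst_rms_top3": True, "pi_ratio_top3": True, "clr_top1": False},
                )
            )
    return calls


def assign_genes(calls: list[SelectionCall], genes: list[GeneModel]) -> list[SelectionCall]:
    """Attach genes overlapping each call span by >= 1 bp (gene span, not CDS)."""
    for call in calls:
        hits = []
        for gm in genes:
            if gm.chrom != call.chrom:
                continue
            lo, hi = gm.span  # 1-based inclusive -> 0-based half-open
            if lo - 1 < call.end and call.start < hi:
                hits.append(gm.gene_id)
        call.genes = hits
    return calls


def psg_list(calls: list[SelectionCall]) -> list[str]:
    """Distinct candidate PSG ids over all calls, in first-seen order."""
    seen: dict[str, None] = {}
    for call in calls:
        for g in call.genes:
            seen.setdefault(g, None)
    return list(seen)


def calls_table(calls: list[SelectionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "focal_group": c.focal_group,
                **{k: int(v) for k, v in c.flags.items()},
                "genes": ",".join(c.genes),
            }
            for c in calls
        ]
    )
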