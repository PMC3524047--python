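"""Publication-shaped outputs: top-window tables, case/control allele
frequencies for the top SNP, cross-cohort window overlap, and the banded
genome track used for side-by-side heat-map comparison of two cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .qc import MISSING

__all__ = [
    "top_windows",
    "allele_freq_by_status",
    "cross_breed_overlap",
    "heatmap_bands",
    "write_bed_track",
]

logger = logging.getLogger(__name__)

BAND_HIGH = 0.14  # >= : strongly associated window (black bar)
BAND_MID = 0.12   # [0.12, 0.14): borderline window (dashed bar)


def _chrom_rank(labels: pd.Series) -> np.ndarray:
    uniq = list(dict.fromkeys(labels.astype(str)))
    numeric = sorted((l for l in uniq if l.isdigit()), key=int)
    other = sorted(l for l in uniq if not l.isdigit())
    rank = {l: i for i, l in enumerate(numeric + other)}
    return labels.astype(str).map(rank).to_numpy()


def top_windows(summary: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Rank windows by posterior mean % of genomic variance, descending;
    ties fall back to (chromosome, Mb) order. Asking for more windows
    than exist returns everything with a warning."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(summary):
        logger.warning(
            "requested top %d windows but only %d available", k, len(summary)
        )
        k = len(summary)
    ranked = (
        summary.assign(_ck=_chrom_rank(summary["chrom"]))
        .sort_values(
            ["mean_pct_var", "_ck", "window_mb"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        .drop(columns="_ck")
        .head(k)
        .reset_index(drop=True)
    )
    return ranked


def allele_freq_by_status(
    calls: np.ndarray, status: np.ndarray, mean_effect: float
) -> tuple[float, float, str, bool]:
    """Unfavourable-allele frequency among cases and among controls.

    The unfavourable allele is the one whose dosage carries a positive
    posterior-mean liability effect: B when ``mean_effect`` > 0 (BB is
    coded +10) and A when it is negative. A zero posterior mean falls
    back to the case-enriched allele and is flagged. Missing calls are
    excluded per group. Returns (freq_cases, freq_controls, allele,
    flagged).
    """
    calls = np.asarray(calls)
    status = np.asarray(status)

    def b_freq(mask: np.ndarray) -> float:
        sub = calls[mask]
        sub = sub[sub != MISSING]
        if sub.size == 0:
            return np.nan
        return float(sub.sum() / (2.0 * sub.size))

    fb_case = b_freq(status == 2)
    fb_ctrl = b_freq(status == 1)
    flagged = False
    if mean_effect > 0:
        allele = "B"
    elif mean_effect < 0:
        allele = "A"
    else:
        allele = "B" if fb_case >= fb_ctrl else "A"
        flagged = True
    if allele == "B":
        return fb_case, fb_ctrl, allele, flagged
    return 1.0 - fb_case, 1.0 - fb_ctrl, allele, flagged


def cross_breed_overlap(
    top_a: pd.DataFrame, top_b: pd.DataFrame, max_dist_mb: int = 15
) -> pd.DataFrame:
    """Same-chromosome pairs of top windows from two cohorts within
    ``max_dist_mb`` Mb of each other, sorted by distance. A window may
    appear in several pairs."""
    rows = []
    for _, a in top_a.iterrows():
        for _, b in top_b.iterrows():
            if str(a["chrom"]) != str(b["chrom"]):
                continue
            dist = abs(int(a["window_mb"]) - int(b["window_mb"]))
            if dist <= max_dist_mb:
                rows.append(
                    {
                        "chrom": str(a["chrom"]),
                        "window_mb_a": int(a["window_mb"]),
                        "window_mb_b": int(b["window_mb"]),
                        "distance_mb": dist,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["chrom", "window_mb_a", "window_mb_b", "distance_mb"]
    )
    return out.sort_values(
        ["distance_mb", "chrom", "window_mb_a"], kind="mergesort"
    ).reset_index(drop=True)


def heatmap_bands(
    summary: pd.DataFrame,
    high: float = BAND_HIGH,
    mid: float = BAND_MID,
) -> pd.DataFrame:
    """Label each window high (>= 0.14% of genomic variance), mid
    ([0.12, 0.14)) or low (< 0.12, graded by value) — the banding used to
    compare cohorts along the genome."""
    out = summary[["window", "chrom", "window_mb", "mean_pct_var"]].copy()
    v = out["mean_pct_var"].to_numpy()
    band = np.where(v >= high, "high", np.where(v >= mid, "mid", "low"))
    out["band"] = band
    # graded shading for the low band: value relative to the mid cut
    out["shade"] = np.clip(v / mid, 0.0, 1.0)
    return out


def write_bed_track(summary: pd.DataFrame, path) -> None:
    """BED4-style window track (0-based half-open) of mean % variance."""
    bed = pd.DataFrame(
        {
            "chrom": summary["chrom"],
            "start": summary["window_mb"].astype(int) * 1_000_000,
            "end": (summary["window_mb"].astype(int) + 1) * 1_000_000,
            "mean_pct_var": summary["mean_pct_var"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
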