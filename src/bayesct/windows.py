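"""1 Mb window partitioning of genomic variance.

SNPs are assigned to consecutive non-overlapping 1 Mb windows by physical
position (window index = floor(bp / 1e6), never spanning chromosomes).
For each thinned MCMC effect sample the windowed genomic values
g_w = Z_w u_w are computed, and the window's share of genomic variance is
var_i(g_w) / var_i(g_total) * 100 with the variance taken among
individuals. Posterior summaries average over ALL thinned samples,
including iterations in which every SNP of the window was excluded
(contributing 0%), and exceedance is the fraction of samples above the
infinitesimal threshold 100/N %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "assign_windows",
    "genome_window_count",
    "window_variance_sample",
    "window_pct_matrix",
    "summarize_windows",
    "infinitesimal_threshold",
    "merge_windows",
]

logger = logging.getLogger(__name__)

MB = 1_000_000


def assign_windows(snp_map: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Tag each SNP with its (chromosome, Mb) window.

    Returns the map (sorted by chromosome then position, with ``window_mb``
    and ``window`` columns added) and the number of distinct SNP-bearing
    windows genome-wide. Duplicate (chrom, pos) entries are logged, not
    fatal.
    """
    if (snp_map["pos"] <= 0).any():
        raise ValueError("positions must be positive integers (1-based bp)")
    out = snp_map.copy()
    out["chrom"] = out["chrom"].astype(str)
    dup = out.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        logger.warning(
            "%d SNPs share a (chromosome, position) coordinate", int(dup.sum())
        )
    out["window_mb"] = out["pos"] // MB
    out["window"] = out["chrom"] + ":" + out["window_mb"].astype(str)
    order = _chrom_sort_key(out["chrom"])
    out = (
        out.assign(_ck=order)
        .sort_values(["_ck", "pos"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    n_windows = out["window"].nunique()
    return out, n_windows


def genome_window_count(chromosomes: list[tuple[str, int]]) -> int:
    """Window count under the genome-length convention (ceil Mb per
    chromosome), the alternative to counting only SNP-bearing windows."""
    return int(sum(int(np.ceil(length)) for _, length in chromosomes))


def _chrom_sort_key(chrom: pd.Series) -> np.ndarray:
    labels = chrom.astype(str)
    uniq = list(dict.fromkeys(labels))
    numeric = sorted((l for l in uniq if l.isdigit()), key=int)
    other = sorted(l for l in uniq if not l.isdigit())
    rank = {l: i for i, l in enumerate(numeric + other)}
    return labels.map(rank).to_numpy()


def _window_slices(windows: np.ndarray) -> dict[str, np.ndarray]:
    """Column indices per window label, preserving map order."""
    out: dict[str, np.ndarray] = {}
    for w in dict.fromkeys(windows):
        out[w] = np.flatnonzero(windows == w)
    return out


def window_variance_sample(
    Z: np.ndarray, u: np.ndarray, windows: np.ndarray
) -> pd.Series:
    """Per-window % of genomic variance for one effect sample.

    An all-zero effect vector (no SNP in the model) yields 0% everywhere
    (0/0 defined as 0).
    """
    Z = np.asarray(Z, dtype=float)
    u = np.asarray(u, dtype=float)
    g_total = Z @ u
    denom = g_total.var(ddof=1)
    labels = list(dict.fromkeys(windows))
    if denom == 0.0:
        return pd.Series(0.0, index=labels)
    vals = {}
    for w, idx in _window_slices(np.asarray(windows)).items():
        g_w = Z[:, idx] @ u[idx]
        vals[w] = 100.0 * g_w.var(ddof=1) / denom
    return pd.Series(vals)


def window_pct_matrix(
    Z: np.ndarray, u_samples: np.ndarray, windows: np.ndarray
) -> pd.DataFrame:
    """Samples x windows matrix of % genomic variance."""
    slices = _window_slices(np.asarray(windows))
    labels = list(slices)
    S = u_samples.shape[0]
    out = np.zeros((S, len(labels)))
    G = Z @ u_samples.T  # animals x samples, total genomic values
    denom = G.var(axis=0, ddof=1)
    for k, (w, idx) in enumerate(slices.items()):
        Gw = Z[:, idx] @ u_samples[:, idx].T
        out[:, k] = Gw.var(axis=0, ddof=1)
    nonzero = denom > 0
    out[nonzero] = 100.0 * out[nonzero] / denom[nonzero, None]
    out[~nonzero] = 0.0
    return pd.DataFrame(out, columns=labels)


def infinitesimal_threshold(n_windows: int) -> float:
    """Expected per-window % under an infinitesimal model: 100/N."""
    if n_windows < 1:
        raise ValueError("need at least one window")
    return 100.0 / n_windows


def summarize_windows(
    pct: pd.DataFrame,
    snp_map: pd.DataFrame,
    threshold: float,
    posterior=None,
    genotypes=None,
    status: np.ndarray | None = None,
) -> pd.DataFrame:
    """Posterior window summary over all thinned samples.

    ``pct`` is the samples x windows matrix from :func:`window_pct_matrix`;
    ``snp_map`` must carry the window assignment. When a
    :class:`~bayesct.bayesc.ChainPosterior` is supplied, the SNP with the
    highest model frequency in each window is reported (ties broken by
    position), and with ``genotypes``/``status`` also the unfavourable
    allele frequency in cases and controls (see
    :func:`bayesct.report.allele_freq_by_status`).
    """
    if pct.shape[0] < 1:
        raise ValueError("need at least one thinned sample")
    rows = []
    grouped = snp_map.groupby("window", sort=False)
    for w in pct.columns:
        sub = grouped.get_group(w)
        row = {
            "window": w,
            "chrom": sub["chrom"].iloc[0],
            "window_mb": int(sub["window_mb"].iloc[0]),
            "n_snps": len(sub),
            "mean_pct_var": float(pct[w].mean()),
            "exceedance": float((pct[w] > threshold).mean()),
        }
        if posterior is not None:
            freq = pd.Series(posterior.model_freq, index=posterior.snp_ids)
            sub = sub.assign(mf=freq.loc[sub["snp"]].to_numpy())
            best = sub.sort_values(
                ["mf", "pos"], ascending=[False, True], kind="mergesort"
            ).iloc[0]
            row.update(
                top_snp=best["snp"],
                top_snp_pos=int(best["pos"]),
                top_snp_model_freq=float(best["mf"]),
            )
            if genotypes is not None and status is not None:
                from .report import allele_freq_by_status

                j = int(np.flatnonzero(genotypes.snp_ids == best["snp"])[0])
                eff = pd.Series(
                    posterior.mean_effect, index=posterior.snp_ids
                ).loc[best["snp"]]
                fc, fctl, allele, flagged = allele_freq_by_status(
                    genotypes.calls[:, j], status, float(eff)
                )
                row.update(
                    unfav_allele=allele,
                    unfav_freq_cases=fc,
                    unfav_freq_controls=fctl,
                    unfav_flagged=flagged,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def merge_windows(
    Z: np.ndarray,
    u_samples: np.ndarray,
    snp_map: pd.DataFrame,
    window_a: str,
    window_b: str,
) -> pd.Series:
    """Per-sample % of genomic variance for the union of two adjacent
    windows on the same chromosome.

    Per sample, var(g_a + g_b) = var(g_a) + var(g_b) + 2 cov(g_a, g_b)
    holds exactly, so the merged share exceeds (falls short of) the sum
    of the parts exactly when the windowed genomic values covary
    positively (negatively).
    """
    wa = snp_map.loc[snp_map["window"] == window_a]
    wb = snp_map.loc[snp_map["window"] == window_b]
    if wa.empty or wb.empty:
        raise ValueError("unknown window label")
    ca, cb = wa["chrom"].iloc[0], wb["chrom"].iloc[0]
    ma, mb_ = int(wa["window_mb"].iloc[0]), int(wb["window_mb"].iloc[0])
    if ca != cb or abs(ma - mb_) != 1:
        raise ValueError("windows must be adjacent on the same chromosome")
    windows = snp_map["window"].to_numpy()
    idx = np.flatnonzero((windows == window_a) | (windows == window_b))
    G = Z @ u_samples.T
    denom = G.var(axis=0, ddof=1)
    Gm = Z[:, idx] @ u_samples[:, idx].T
    num = Gm.var(axis=0, ddof=1)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = 100.0 * num[nz] / denom[nz]
    return pd.Series(out, name=f"{window_a}+{window_b}")
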