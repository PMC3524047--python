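"""Synthetic matched case-control cohorts with half-sib family structure.

Emulates the data layout of an equine insect-bite-hypersensitivity GWAS:
paternal half-sib families (many sires, one unique dam per offspring),
SNP-chip genotypes on 31 autosomes plus X, a liability-threshold binary
phenotype with a handful of planted QTL windows, and matching factors
(coat colour, withers height, sex, premise, import status, age, scoring
date, veterinarian) recorded per animal.

The liability of animal i is l_i = g_i + e_i with e_i ~ N(0, 1) and
g_i = sum_j beta_j z_ij over QTL and polygenic background SNPs, rescaled
so that var(g) / (var(g) + 1) equals the requested liability-scale
heritability. Case status is assigned by thresholding the liability at
the empirical quantile that yields the requested case fraction, mimicking
a case-control design that samples to a target prevalence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DEFAULT_CHROMOSOMES
from .qc import MISSING, GenotypeMatrix

__all__ = ["SimulationConfig", "simulate_population", "inject_missingness"]

COLOURS = ["black", "chestnut", "bay", "grey"]
HEIGHTS = ["small", "medium", "large"]

# Import-status assignment in confounder mode: P(imported | control) and
# P(imported | case) chosen to give an odds ratio of ~8 at ~13% overall
# import frequency, the regime the stratification screen must flag.
CONFOUNDER_P_IMPORT_CONTROL = 0.035
CONFOUNDER_P_IMPORT_CASE = 0.225


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort."""

    n_sires: int = 40
    offspring_per_sire: int = 5
    n_snps: int = 10_000
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_CHROMOSOMES)
    )
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    qtl_spec: list[tuple[str, int, float]] = field(default_factory=list)
    h2_liability: float = 0.24
    case_fraction: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    # founder LD: 0 disables (site-independent draws); >0 makes blocks of
    # that many adjacent SNPs share a latent uniform, inducing strong
    # positive LD within each block.
    ld_block_size: int = 0
    # number of causal SNPs carrying each QTL window's variance
    qtl_snps_per_window: int = 1
    # tie import status to case odds (tests the exclusion path)
    confounded_import: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_liability < 1.0):
            raise ValueError("h2_liability must be in [0, 1)")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        qtl_total = sum(frac for _, _, frac in self.qtl_spec)
        if qtl_total > self.h2_liability + 1e-12:
            raise ValueError(
                "sum of QTL variance fractions exceeds h2_liability"
            )
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        lengths = dict((str(c), l) for c, l in self.chromosomes)
        for chrom, start_mb, frac in self.qtl_spec:
            if str(chrom) not in lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not in genome")
            if not (0 <= start_mb < lengths[str(chrom)]):
                raise ValueError(
                    f"QTL window {chrom}:{start_mb} Mb outside chromosome"
                )
            if frac < 0:
                raise ValueError("QTL variance fractions must be >= 0")
        if self.n_snps < len(self.chromosomes):
            raise ValueError(
                "n_snps too small to place at least one SNP per chromosome"
            )

    @property
    def n_animals(self) -> int:
        return self.n_sires * self.offspring_per_sire


def _build_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place SNPs on chromosomes proportionally to length, uniform positions."""
    lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    raw = config.n_snps * lengths / lengths.sum()
    counts = np.maximum(np.floor(raw).astype(int), 1)
    # largest-remainder top-up to hit n_snps exactly
    deficit = config.n_snps - counts.sum()
    if deficit > 0:
        order = np.argsort(-(raw - np.floor(raw)))
        for idx in order[:deficit]:
            counts[idx] += 1
    elif deficit < 0:
        order = np.argsort(raw - np.floor(raw))
        i = 0
        while deficit < 0:
            idx = order[i % len(order)]
            if counts[idx] > 1:
                counts[idx] -= 1
                deficit += 1
            i += 1
    rows = []
    snp_idx = 0
    for (chrom, length), count in zip(config.chromosomes, counts):
        pos = np.sort(
            rng.choice(length * 1_000_000, size=count, replace=False)
        ) + 1  # 1-based bp
        for p in pos:
            rows.append((f"SNP{snp_idx:06d}", str(chrom), int(p)))
            snp_idx += 1
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def _draw_haplotypes(
    n_hap: int,
    p: np.ndarray,
    snp_map: pd.DataFrame,
    block: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes; optional block-LD via a shared latent uniform."""
    n_snps = p.size
    if block <= 0:
        return (rng.random((n_hap, n_snps)) < p).astype(np.int8)
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    chrom_codes = snp_map["chrom"].to_numpy()
    start = 0
    for chrom in pd.unique(chrom_codes):
        idx = np.flatnonzero(chrom_codes == chrom)
        for b0 in range(0, idx.size, block):
            cols = idx[b0 : b0 + block]
            u = rng.random((n_hap, 1))
            hap[:, cols] = (u < p[cols]).astype(np.int8)
        start += idx.size
    return hap


def _transmit(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    snp_map: pd.DataFrame,
    block: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a parent's two haplotypes (free recombination between
    sites, or between blocks when block-LD is on)."""
    n_snps = hap_a.size
    if block <= 0:
        pick = rng.integers(0, 2, size=n_snps).astype(bool)
    else:
        pick = np.empty(n_snps, dtype=bool)
        chrom_codes = snp_map["chrom"].to_numpy()
        for chrom in pd.unique(chrom_codes):
            idx = np.flatnonzero(chrom_codes == chrom)
            for b0 in range(0, idx.size, block):
                cols = idx[b0 : b0 + block]
                pick[cols] = rng.integers(0, 2) == 1
    return np.where(pick, hap_a, hap_b)


def _select_qtl_snps(
    snp_map: pd.DataFrame, config: SimulationConfig
) -> list[np.ndarray]:
    """For each QTL window, the causal SNP indices (nearest window centre)."""
    chosen: list[np.ndarray] = []
    for chrom, start_mb, _frac in config.qtl_spec:
        lo = start_mb * 1_000_000
        hi = lo + 1_000_000
        in_win = np.flatnonzero(
            (snp_map["chrom"].to_numpy() == str(chrom))
            & (snp_map["pos"].to_numpy() > lo)
            & (snp_map["pos"].to_numpy() <= hi)
        )
        if in_win.size == 0:
            raise ValueError(
                f"no SNP lands in QTL window {chrom}:{start_mb} Mb; "
                "increase n_snps"
            )
        centre = lo + 500_000
        dist = np.abs(snp_map["pos"].to_numpy()[in_win] - centre)
        take = in_win[np.argsort(dist)][: config.qtl_snps_per_window]
        chosen.append(np.sort(take))
    return chosen


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one cohort.

    Returns ``(genotypes, snp_map, phenotypes, truth)`` where ``truth``
    records the causal effects, QTL windows, liability threshold and the
    realized heritability, enabling downstream parameter-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    snp_map = _build_map(config, rng)
    n = config.n_animals
    n_snps = config.n_snps

    lo, hi = config.allele_freq_range
    p = rng.uniform(lo, hi, size=n_snps)  # founder B-allele frequency

    block = config.ld_block_size
    sire_hap = _draw_haplotypes(2 * config.n_sires, p, snp_map, block, rng)
    dam_hap = _draw_haplotypes(2 * n, p, snp_map, block, rng)

    calls = np.empty((n, n_snps), dtype=np.int8)
    sire_ids = np.empty(n, dtype=object)
    animal_ids = np.array([f"A{i:05d}" for i in range(n)], dtype=object)
    for i in range(n):
        s = i // config.offspring_per_sire
        sire_ids[i] = f"S{s:04d}"
        pat = _transmit(sire_hap[2 * s], sire_hap[2 * s + 1], snp_map, block, rng)
        mat = _transmit(dam_hap[2 * i], dam_hap[2 * i + 1], snp_map, block, rng)
        calls[i] = pat + mat  # 0/1/2 copies of the B allele

    # --- liability -------------------------------------------------------
    h2 = config.h2_liability
    beta = np.zeros(n_snps)
    g = np.zeros(n)
    qtl_snp_sets = _select_qtl_snps(snp_map, config) if config.qtl_spec else []
    var_g_target = h2 / (1.0 - h2) if h2 > 0 else 0.0
    var_l_target = var_g_target + 1.0

    zc = calls.astype(float)
    zc -= zc.mean(axis=0)  # centred allele counts, causal scale

    if h2 > 0:
        for (chrom, start_mb, frac), idx in zip(config.qtl_spec, qtl_snp_sets):
            if frac == 0:
                continue
            raw = rng.choice([-1.0, 1.0], size=idx.size)
            g_q = zc[:, idx] @ raw
            v = g_q.var()
            if v <= 0:
                raise ValueError(
                    f"QTL window {chrom}:{start_mb} Mb is monomorphic in sample"
                )
            scale = np.sqrt(frac * var_l_target / v)
            beta[idx] += raw * scale
            g += g_q * scale
        poly_frac = h2 - sum(frac for _, _, frac in config.qtl_spec)
        if poly_frac > 1e-12:
            qtl_all = (
                np.concatenate(qtl_snp_sets) if qtl_snp_sets else np.array([], int)
            )
            bg = np.setdiff1d(np.arange(n_snps), qtl_all)
            raw = rng.standard_normal(bg.size)
            g_bg = zc[:, bg] @ raw
            v = g_bg.var()
            scale = np.sqrt(poly_frac * var_l_target / v)
            beta[bg] += raw * scale
            g += g_bg * scale

    e = rng.standard_normal(n)
    liability = g + e
    threshold = float(np.quantile(liability, 1.0 - config.case_fraction))
    status = np.where(liability > threshold, 2, 1)  # 2 = case, 1 = control

    # --- matching factors (independent of liability by default) ----------
    n_premises = max(n // 3, 1)
    pheno = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "sire_id": sire_ids,
            "status": status,
            "colour": rng.choice(COLOURS, size=n),
            "height": rng.choice(HEIGHTS, size=n),
            "sex": rng.choice(["F", "M"], size=n, p=[0.65, 0.35]),
            "premise": [f"P{rng.integers(0, n_premises):03d}" for _ in range(n)],
            "age": rng.integers(3, 21, size=n),
            "year": rng.choice([2009, 2010], size=n),
            "month": rng.choice([9, 10, 11], size=n),
            "vet": rng.choice(["V1", "V2"], size=n, p=[0.95, 0.05]),
        }
    )
    if config.confounded_import:
        p_imp = np.where(
            status == 2, CONFOUNDER_P_IMPORT_CASE, CONFOUNDER_P_IMPORT_CONTROL
        )
    else:
        p_imp = np.full(n, 0.13)
    pheno["import_status"] = np.where(rng.random(n) < p_imp, "yes", "no")

    genotypes = GenotypeMatrix(
        animal_ids=animal_ids.astype(str),
        snp_ids=snp_map["snp"].to_numpy().astype(str),
        calls=calls,
    )
    if config.missing_rate > 0:
        genotypes = inject_missingness(
            genotypes, config.missing_rate, seed=int(rng.integers(2**31))
        )

    var_l = float(liability.var())
    truth = {
        "config": dataclasses.asdict(config),
        "beta_index": np.flatnonzero(beta).tolist(),
        "beta_value": beta[beta != 0].tolist(),
        "qtl_windows": [
            {"chrom": str(c), "start_mb": int(m), "frac": float(f),
             "snps": snp_map["snp"].to_numpy()[idx].tolist()}
            for (c, m, f), idx in zip(config.qtl_spec, qtl_snp_sets)
        ],
        "threshold": threshold,
        "realized_h2": float(g.var() / var_l) if var_l > 0 else 0.0,
        "var_g": float(g.var()),
        "founder_freq": p.tolist(),
    }
    return genotypes, snp_map, pheno, truth


def inject_missingness(
    genotypes: GenotypeMatrix, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Mask each call independently with probability ``missing_rate``."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return genotypes
    rng = np.random.default_rng(seed)
    mask = rng.random(genotypes.calls.shape) < missing_rate
    calls = genotypes.calls.copy()
    calls[mask] = MISSING
    return GenotypeMatrix(
        animal_ids=genotypes.animal_ids,
        snp_ids=genotypes.snp_ids,
        calls=calls,
    )
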