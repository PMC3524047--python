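"""SNP/animal quality control and genotype covariate coding.

Calls are stored as B-allele dosage: 0 = AA, 1 = AB, 2 = BB, -1 = missing.
SNPs failing call-rate (< 0.90, strict) or minor allele frequency
(<= 0.02, inclusive) are removed; survivors are coded AA = -10, AB = 0,
BB = +10 with missing entries imputed to the SNP's observed mean coded
value, the covariate scale the sampler consumes. No further centring or
scaling is applied — the model's overall mean absorbs column means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "CodedMatrix",
    "compute_call_rate",
    "compute_maf",
    "filter_snps",
    "filter_animals",
    "encode_genotypes",
]

MISSING: int = -1

DEFAULT_CALL_RATE_MIN = 0.90  # removed when strictly below
DEFAULT_MAF_MAX = 0.02        # removed when <= this value


@dataclass(frozen=True)
class GenotypeMatrix:
    """Animals x SNPs calls in {0, 1, 2, MISSING} (B-allele dosage)."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("calls shape inconsistent with id vectors")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.animal_ids, self.snp_ids[index], self.calls[:, index]
        )

    def take_animals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.animal_ids[index], self.snp_ids, self.calls[index, :]
        )


@dataclass(frozen=True)
class CodedMatrix:
    """Real-valued genotype covariates: AA=-10, AB=0, BB=+10, missing imputed.

    ``p`` is the per-SNP B-allele frequency among observed calls.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    Z: np.ndarray
    p: np.ndarray

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column_variances(self, ddof: int = 0) -> np.ndarray:
        return self.Z.var(axis=0, ddof=ddof)


def compute_call_rate(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of non-missing calls per SNP and per animal."""
    if calls.size == 0:
        raise ValueError("empty genotype matrix")
    observed = calls != MISSING
    per_snp = observed.mean(axis=0)
    per_animal = observed.mean(axis=1)
    return per_snp, per_animal


def compute_maf(calls: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency over observed calls.

    All-missing SNPs yield NaN (undefined frequency).
    """
    calls = np.atleast_2d(calls)
    observed = calls != MISSING
    n_obs = observed.sum(axis=0)
    b_count = np.where(observed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, b_count / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_snps(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
    maf_max: float = DEFAULT_MAF_MAX,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Remove SNPs with call-rate < ``call_rate_min`` or MAF <= ``maf_max``.

    Returns the filtered matrix, the matching map subset, and an exclusion
    log (snp, reason, value). Call-rate failures take precedence in the log
    when a SNP fails both rules. Intended to be applied per cohort
    independently (breed-specific QC).
    """
    call_rate, _ = compute_call_rate(genotypes.calls)
    maf = compute_maf(genotypes.calls)
    fail_cr = call_rate < call_rate_min
    fail_maf = np.isnan(maf) | (maf <= maf_max)
    records = []
    for j in np.flatnonzero(fail_cr | fail_maf):
        if fail_cr[j]:
            records.append((genotypes.snp_ids[j], "call_rate", call_rate[j]))
        else:
            records.append((genotypes.snp_ids[j], "maf", maf[j]))
    log = pd.DataFrame(records, columns=["snp", "reason", "value"])
    keep = ~(fail_cr | fail_maf)
    if not keep.any():
        raise ValueError("no SNP survives quality control")
    filtered = genotypes.take_snps(keep)
    map_out = snp_map.set_index("snp").loc[filtered.snp_ids].reset_index()
    return filtered, map_out, log


def filter_animals(
    genotypes: GenotypeMatrix, call_rate_min: float = DEFAULT_CALL_RATE_MIN
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop animals whose call-rate is not above ``call_rate_min``.

    Applied once, before SNP filtering. Returns the kept matrix and the
    ids of removed animals.
    """
    _, per_animal = compute_call_rate(genotypes.calls)
    keep = per_animal > call_rate_min
    removed = genotypes.animal_ids[~keep]
    return genotypes.take_animals(keep), removed


def encode_genotypes(genotypes: GenotypeMatrix) -> CodedMatrix:
    """Code AA=-10, AB=0, BB=+10; impute missing to observed column mean."""
    calls = genotypes.calls
    observed = calls != MISSING
    if not observed.any(axis=0).all():
        raise ValueError("encode_genotypes requires >= 1 observed call per SNP")
    coded = (calls.astype(np.float64) - 1.0) * 10.0
    n_obs = observed.sum(axis=0)
    col_mean = np.where(observed, coded, 0.0).sum(axis=0) / n_obs
    Z = np.where(observed, coded, col_mean)
    p = np.where(observed, calls, 0).sum(axis=0) / (2.0 * n_obs)
    return CodedMatrix(
        animal_ids=genotypes.animal_ids,
        snp_ids=genotypes.snp_ids,
        Z=Z,
        p=p,
    )
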