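"""Population-stratification diagnostics for matched case-control cohorts.

Implements identity-by-state genomic kinship on genotypes coded 0/0.5/1,
classical multidimensional scaling of the derived distance matrix, a
logistic screen of the matching factors (univariable and joint
multivariable, Wald tests), and a factor-level exclusion filter such as
the removal of imported animals when import status associates with case
status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .genome import is_autosome
from .qc import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "MdsResult",
    "compute_kinship",
    "kinship_to_distance",
    "classical_mds",
    "screen_matching_factors",
    "exclude_by_factor",
    "restrict_to_autosomes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KinshipMatrix:
    animal_ids: np.ndarray
    f: np.ndarray  # symmetric animals x animals


@dataclass(frozen=True)
class MdsResult:
    animal_ids: np.ndarray
    coords: np.ndarray       # animals x 2, principal coordinates
    eigenvalues: np.ndarray  # all eigenvalues, descending


def restrict_to_autosomes(
    genotypes: GenotypeMatrix, snp_map: pd.DataFrame
) -> GenotypeMatrix:
    """Drop X-chromosome and monomorphic SNPs before kinship."""
    auto = snp_map["chrom"].map(is_autosome).to_numpy()
    gm = genotypes.take_snps(auto)
    observed = gm.calls != MISSING
    n_obs = observed.sum(axis=0)
    b = np.where(observed, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, b / (2.0 * n_obs), 0.0)
    poly = (p > 0.0) & (p < 1.0)
    return gm.take_snps(poly)


def compute_kinship(
    genotypes: GenotypeMatrix, p: np.ndarray | None = None
) -> KinshipMatrix:
    """Genomic IBS kinship on genotypes coded x in {0, 1/2, 1}.

    f(i,j) = mean over SNPs observed in both animals of
    (x_ik - p_k)(x_jk - p_k) / (p_k (1 - p_k)).

    Averaging over the pairwise-complete SNP count keeps the statistic
    independent of panel size. Monomorphic SNPs are a precondition
    violation (zero denominator).
    """
    calls = genotypes.calls
    observed = calls != MISSING
    n_obs = observed.sum(axis=0)
    if p is None:
        if (n_obs == 0).any():
            raise ValueError(
                "all-missing SNP in kinship input (frequency undefined)"
            )
        p = np.where(observed, calls, 0).sum(axis=0) / (2.0 * n_obs)
    p = np.asarray(p, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("monomorphic SNP in kinship input (p in {0,1})")
    x = calls / 2.0
    y = np.where(observed, (x - p) / np.sqrt(p * (1.0 - p)), 0.0)
    num = y @ y.T
    k_pair = observed.astype(np.float64) @ observed.astype(np.float64).T
    if (k_pair == 0).any():
        raise ValueError("animal pair with no jointly observed SNP")
    return KinshipMatrix(genotypes.animal_ids, num / k_pair)


def kinship_to_distance(kinship: KinshipMatrix | np.ndarray) -> np.ndarray:
    """Monotone-decreasing transform d = max(f) - f with zero diagonal.

    Classical MDS is invariant to the additive constant after double
    centring, so any decreasing affine transform yields the same
    principal coordinates.
    """
    f = kinship.f if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
    if not np.allclose(f, f.T):
        raise ValueError("kinship matrix must be symmetric")
    d = f.max() - f
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(
    distance: np.ndarray, n_components: int = 2,
    animal_ids: np.ndarray | None = None,
) -> MdsResult:
    """Principal-coordinates analysis of a distance matrix.

    Double-centres -0.5 * J d^2 J, eigendecomposes, truncates negative
    eigenvalues to zero, and scales the top eigenvectors by the square
    root of their eigenvalues.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    if vals[0] > 0:  # numerically-zero axes collapse to exact zero
        vals[vals < vals[0] * 1e-12] = 0.0
    vecs = vecs[:, order]
    coords = vecs[:, :n_components] * np.sqrt(vals[:n_components])
    if animal_ids is None:
        animal_ids = np.arange(n)
    return MdsResult(np.asarray(animal_ids), coords, vals)


def _fit_wald(formula: str, data: pd.DataFrame) -> sm.GLM:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, data=data, family=sm.families.Binomial())
        return model.fit(maxiter=200)


def _term_pvalue(result, term: str) -> float:
    """Joint Wald p-value for all coefficients belonging to one term."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = result.wald_test_terms(scalar=True).table
    for name in table.index:
        if name == term or name.startswith(f"C({term}") or name == f"C({term})":
            return float(table.loc[name, "pvalue"])
    raise KeyError(f"term {term!r} not found in fitted model")


def _estimable(result) -> bool:
    # separation / non-identified levels show up as enormous standard errors
    return bool(np.all(np.isfinite(result.bse)) and np.all(result.bse < 1e3))


def screen_matching_factors(
    phenotypes: pd.DataFrame,
    factors: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Logistic screen of matching factors against case status.

    Fits a binomial GLM with logit link per factor (univariable) and one
    joint multivariable model; reports Wald p-values and flags factors
    significant at ``alpha``. Categorical factors are tested jointly
    across their levels. Perfectly separating or non-identified factors
    are reported as non-estimable rather than raising.
    """
    data = phenotypes.copy()
    data["case"] = (data["status"] == 2).astype(int)

    def term(f: str) -> str:
        return f if pd.api.types.is_numeric_dtype(data[f]) else f"C({f})"

    uni_p: dict[str, float] = {}
    uni_ok: dict[str, bool] = {}
    for f in factors:
        if data[f].nunique() < 2:
            uni_p[f] = 1.0
            uni_ok[f] = True
            continue
        try:
            res = _fit_wald(f"case ~ {term(f)}", data)
            uni_ok[f] = _estimable(res)
            uni_p[f] = _term_pvalue(res, f) if uni_ok[f] else np.nan
        except Exception:
            uni_ok[f] = False
            uni_p[f] = np.nan

    multi_terms = [f for f in factors if data[f].nunique() >= 2]
    multi_p: dict[str, float] = {f: np.nan for f in factors}
    multi_ok: dict[str, bool] = {f: False for f in factors}
    if multi_terms:
        try:
            res = _fit_wald(
                "case ~ " + " + ".join(term(f) for f in multi_terms), data
            )
            ok = _estimable(res)
            for f in multi_terms:
                multi_ok[f] = ok
                multi_p[f] = _term_pvalue(res, f) if ok else np.nan
        except Exception:
            pass
    for f in factors:
        if data[f].nunique() < 2:
            multi_p[f] = 1.0
            multi_ok[f] = True

    out = pd.DataFrame(
        {
            "factor": factors,
            "p_univariable": [uni_p[f] for f in factors],
            "p_multivariable": [multi_p[f] for f in factors],
            "estimable": [uni_ok[f] for f in factors],
        }
    )
    out["flagged"] = out["estimable"] & (out["p_univariable"] < alpha)
    return out


def exclude_by_factor(
    phenotypes: pd.DataFrame,
    factor: str,
    level,
    strict: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Remove every animal whose ``factor`` equals ``level``.

    Returns the filtered table and before/after case-control counts.
    """
    if factor not in phenotypes.columns:
        raise KeyError(f"factor {factor!r} not in phenotype table")
    present = (phenotypes[factor] == level).any()
    if not present and strict:
        raise ValueError(f"level {level!r} absent from factor {factor!r}")
    before_cases = int((phenotypes["status"] == 2).sum())
    before_controls = int((phenotypes["status"] == 1).sum())
    kept = phenotypes.loc[phenotypes[factor] != level].reset_index(drop=True)
    after_cases = int((kept["status"] == 2).sum())
    after_controls = int((kept["status"] == 1).sum())
    if before_cases > 0 and after_cases == 0:
        logger.warning(
            "excluding %s=%r removed every case", factor, level
        )
    counts = {
        "cases_before": before_cases,
        "controls_before": before_controls,
        "cases_after": after_cases,
        "controls_after": after_controls,
        "removed_cases": before_cases - after_cases,
        "removed_controls": before_controls - after_controls,
    }
    return kept, counts
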