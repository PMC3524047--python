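"""Bayes-C mixture regression under a probit liability threshold model.

The binary phenotype y_i (case/control) is linked to a latent liability
l_i = mu + sum_j z_ij u_j delta_j + e_i with e_i ~ N(0, 1) fixed (the
residual variance is not identifiable on the liability scale) and the
threshold at 0. Each SNP effect u_j is zero with prior probability pi
and N(0, sigma_u^2) otherwise; sigma_u^2 carries a scaled inverse
chi-square prior with nu_u degrees of freedom and scale S_u^2 derived
from the liability-scale heritability.

Gibbs cycle per iteration: truncated-normal liabilities given status,
the overall mean (flat prior), each SNP in genome map order with delta
sampled from its marginal (effect integrated out) and u from its
conditional normal when included, then sigma_u^2 from its conjugate
scaled inverse chi-square. The hot loop is compiled with numba; a single
seeded RandomState drives the whole chain, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .qc import CodedMatrix

__all__ = [
    "BayesCConfig",
    "ChainPosterior",
    "derive_prior_scale",
    "sample_liabilities",
    "gibbs_update_snp",
    "update_sigma_u2",
    "run_chain",
]


@dataclass(frozen=True)
class BayesCConfig:
    """Sampler settings; defaults mirror a full-length production chain."""

    pi: float = 0.999
    chain_length: int = 200_000
    burn_in: int = 20_000
    window_thin: int = 100
    nu_u: float = 4.0
    h2_prior: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must be in (0, 1)")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.window_thin < 1:
            raise ValueError("window_thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return self.chain_length - self.burn_in

    @property
    def n_thinned(self) -> int:
        return self.n_kept // self.window_thin


@dataclass(frozen=True)
class ChainPosterior:
    """Posterior summaries and thinned samples from one chain."""

    snp_ids: np.ndarray
    model_freq: np.ndarray       # P(delta_j = 1 | data), post burn-in
    mean_effect: np.ndarray      # posterior mean of u_j (zeros included)
    u_samples: np.ndarray        # thinned post-burn-in effect vectors, S x K
    model_size: np.ndarray       # per-iteration count of included SNPs
    sigma_u2: np.ndarray         # per-iteration common effect variance
    mu: np.ndarray               # per-iteration overall mean
    pct_var_all_snps: float      # posterior mean of 100*var(g)/(var(g)+1)
    prior_sigma_a2: float
    prior_S_u2: float
    config: BayesCConfig
    min_case_liability: float    # diagnostics: liability constraint
    max_control_liability: float

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "model_frequency": self.model_freq,
                "mean_effect": self.mean_effect,
            }
        )


def derive_prior_scale(
    h2_prior: float, n_snps: int, pi: float, coded: CodedMatrix | np.ndarray
) -> tuple[float, float]:
    """Prior additive variance and effect-variance scale.

    With the liability residual fixed at 1, the additive genetic variance
    implied by heritability h2 is sigma_a^2 = h2 / (1 - h2). The scale of
    the effect-variance prior spreads sigma_a^2 over the K(1 - pi) SNPs
    expected in the model: S_u^2 = sigma_a^2 / (K (1 - pi) vbar), where
    vbar is the mean per-SNP covariate variance — the coding-scale
    analogue of 2*pbar*qbar for allele-content covariates, which keeps
    the implied genetic variance invariant to the +/-10 coding.
    """
    if not (0.0 < h2_prior < 1.0):
        raise ValueError("h2_prior must be strictly inside (0, 1)")
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    Z = coded.Z if isinstance(coded, CodedMatrix) else np.asarray(coded)
    vbar = float(Z.var(axis=0, ddof=0).mean())
    if vbar <= 0:
        raise ValueError("zero mean covariate variance")
    sigma_a2 = h2_prior / (1.0 - h2_prior)
    s_u2 = sigma_a2 / (n_snps * (1.0 - pi) * vbar)
    return sigma_a2, s_u2


def sample_liabilities(
    status: np.ndarray, eta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw liabilities ~ N(eta, 1) truncated by case/control status.

    Cases (status 2) are truncated to (0, inf), controls (status 1) to
    (-inf, 0]. Vectorised via the inverse-CDF of the truncated normal.
    """
    status = np.asarray(status)
    eta = np.asarray(eta, dtype=float)
    is_case = status == 2
    a = np.where(is_case, -eta, -np.inf)
    b = np.where(is_case, np.inf, -eta)
    return eta + stats.truncnorm.rvs(a, b, random_state=rng)


def gibbs_update_snp(
    z: np.ndarray,
    residual: np.ndarray,
    u_current: float,
    sigma_u2: float,
    pi: float,
    rng: np.random.Generator,
) -> tuple[int, float, np.ndarray]:
    """One Bernoulli/normal update for a single SNP.

    ``residual`` is the full-model residual (it includes -z*u_current when
    the SNP is currently in the model). Returns (delta, u, residual) with
    the residual updated in place for the new effect. The inclusion
    indicator is drawn from its marginal with the effect integrated out:
    odds = (1-pi)/pi * sqrt(lam/(C+lam)) * exp(rhs^2 / (2 (C+lam)))
    with C = z'z, lam = 1/sigma_u2, rhs = z'residual + C*u_current.
    """
    z = np.asarray(z, dtype=float)
    if 1.0 - pi <= 0.0:  # pi -> 1 limit: never include
        return 0, 0.0, residual + z * u_current
    c = float(z @ z)
    lam = 1.0 / sigma_u2
    rhs = float(z @ residual) + c * u_current
    v1 = c + lam
    log_odds = (
        math.log1p(-pi) - math.log(pi)
        + 0.5 * (math.log(lam) - math.log(v1))
        + 0.5 * rhs * rhs / v1
    )
    if not math.isfinite(log_odds):
        raise FloatingPointError("non-finite inclusion likelihood ratio")
    p_incl = 1.0 / (1.0 + math.exp(-log_odds)) if log_odds < 35 else 1.0
    if rng.random() < p_incl:
        u_new = rhs / v1 + rng.standard_normal() / math.sqrt(v1)
        residual = residual - z * (u_new - u_current)
        return 1, u_new, residual
    residual = residual + z * u_current
    return 0, 0.0, residual


def update_sigma_u2(
    u: np.ndarray,
    delta: np.ndarray,
    nu_u: float,
    s_u2: float,
    rng: np.random.Generator,
) -> float:
    """Scaled inverse chi-square draw for the common SNP-effect variance.

    Posterior df = nu_u + m and scale (nu_u S_u^2 + sum of included u^2)
    / (nu_u + m), with m the number of included effects.
    """
    u = np.asarray(u, dtype=float)
    delta = np.asarray(delta)
    m = int(delta.sum())
    ssq = float((u[delta.astype(bool)] ** 2).sum())
    df = nu_u + m
    scale = (nu_u * s_u2 + ssq) / df
    return df * scale / rng.chisquare(df)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rtnorm_pos(mu: float) -> float:
    """N(mu, 1) truncated to (0, inf); Robert's exponential rejection in
    the far tail, plain rejection otherwise."""
    a = -mu
    if a < 0.45:
        while True:
            x = np.random.standard_normal()
            if x > a:
                return mu + x
    else:
        alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
        while True:
            z = a - math.log(np.random.random()) / alpha
            d = z - alpha
            if np.random.random() <= math.exp(-0.5 * d * d):
                return mu + z


@njit(cache=True)
def _chain_kernel(
    Zt,            # K x n, C-contiguous (SNP-major) coded covariates
    is_case,       # n bool
    order,         # K int64, genome map order of SNP visits
    pi,
    nu_u,
    s_u2,
    n_iter,
    burn_in,
    thin,
    seed,
):
    np.random.seed(seed)
    K, n = Zt.shape
    c = np.empty(K)
    for j in range(K):
        s = 0.0
        for i in range(n):
            s += Zt[j, i] * Zt[j, i]
        c[j] = s

    u = np.zeros(K)
    delta = np.zeros(K, np.uint8)
    mu = 0.0
    sigma_u2 = s_u2 * nu_u / (nu_u - 2.0) if nu_u > 2.0 else s_u2
    liab = np.empty(n)
    r = np.empty(n)
    for i in range(n):
        liab[i] = 0.8 if is_case[i] else -0.8
        r[i] = liab[i]  # mu = 0, u = 0

    n_kept = n_iter - burn_in
    n_samples = n_kept // thin
    u_store = np.zeros((n_samples, K))
    incl_count = np.zeros(K, np.int64)
    u_sum = np.zeros(K)
    model_size = np.empty(n_iter, np.int64)
    sigma_tr = np.empty(n_iter)
    mu_tr = np.empty(n_iter)
    pct_sum = 0.0
    min_case_l = np.inf
    max_ctrl_l = -np.inf
    bad_snp = -1

    log_prior_odds = math.log(1.0 - pi) - math.log(pi)

    for it in range(n_iter):
        # --- liabilities -------------------------------------------------
        for i in range(n):
            eta = liab[i] - r[i]
            if is_case[i]:
                lnew = _rtnorm_pos(eta)
            else:
                lnew = -_rtnorm_pos(-eta)
            r[i] += lnew - liab[i]
            liab[i] = lnew
        # --- overall mean (flat prior) -----------------------------------
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        shift = rbar + np.random.standard_normal() / math.sqrt(n)
        for i in range(n):
            r[i] -= shift
        mu += shift
        # --- SNP effects --------------------------------------------------
        lam = 1.0 / sigma_u2
        m = 0
        ssq = 0.0
        for idx in range(K):
            j = order[idx]
            uj = u[j]
            s = 0.0
            for i in range(n):
                s += Zt[j, i] * r[i]
            rhs = s + c[j] * uj
            v1 = c[j] + lam
            log_odds = (
                log_prior_odds
                + 0.5 * (math.log(lam) - math.log(v1))
                + 0.5 * rhs * rhs / v1
            )
            if not math.isfinite(log_odds):
                bad_snp = j
            if log_odds > 35.0:
                p_incl = 1.0
            elif log_odds < -35.0:
                p_incl = 0.0
            else:
                p_incl = 1.0 / (1.0 + math.exp(-log_odds))
            if np.random.random() < p_incl:
                unew = rhs / v1 + np.random.standard_normal() / math.sqrt(v1)
                du = unew - uj
                for i in range(n):
                    r[i] -= Zt[j, i] * du
                u[j] = unew
                delta[j] = 1
                m += 1
                ssq += unew * unew
            else:
                if uj != 0.0:
                    for i in range(n):
                        r[i] += Zt[j, i] * uj
                u[j] = 0.0
                delta[j] = 0
        # --- common effect variance --------------------------------------
        df = nu_u + m
        sigma_u2 = (nu_u * s_u2 + ssq) / np.random.chisquare(df)

        model_size[it] = m
        sigma_tr[it] = sigma_u2
        mu_tr[it] = mu

        if it >= burn_in:
            for j in range(K):
                if delta[j] == 1:
                    incl_count[j] += 1
                    u_sum[j] += u[j]
            # genomic values g_i = liab_i - mu - r_i; share of liability var
            gbar = 0.0
            for i in range(n):
                gbar += liab[i] - mu - r[i]
            gbar /= n
            vg = 0.0
            for i in range(n):
                d = liab[i] - mu - r[i] - gbar
                vg += d * d
            vg /= n - 1
            pct_sum += 100.0 * vg / (vg + 1.0)
            for i in range(n):
                if is_case[i]:
                    if liab[i] < min_case_l:
                        min_case_l = liab[i]
                else:
                    if liab[i] > max_ctrl_l:
                        max_ctrl_l = liab[i]
            kept = it - burn_in + 1
            if kept % thin == 0:
                srow = kept // thin - 1
                if srow < n_samples:
                    for j in range(K):
                        u_store[srow, j] = u[j]

    return (
        u_store,
        incl_count,
        u_sum,
        model_size,
        sigma_tr,
        mu_tr,
        pct_sum / n_kept,
        min_case_l,
        max_ctrl_l,
        bad_snp,
    )


def run_chain(
    coded: CodedMatrix,
    status: np.ndarray,
    config: BayesCConfig,
    snp_map: pd.DataFrame | None = None,
) -> ChainPosterior:
    """Run one Gibbs chain on a QC'd, encoded cohort.

    ``status`` uses 1 = control, 2 = case; animals with any other status
    are excluded before sampling. SNPs are visited in genome map order
    when ``snp_map`` (columns chrom, pos aligned with ``coded.snp_ids``)
    is given, otherwise in storage order. Deterministic given
    ``config.seed``.
    """
    status = np.asarray(status)
    valid = (status == 1) | (status == 2)
    Z = coded.Z
    if not valid.all():
        status = status[valid]
        Z = Z[valid]
    if Z.shape[0] < 2:
        raise ValueError("need at least two animals with known status")

    K = coded.n_snps
    if snp_map is not None:
        m = snp_map.set_index("snp").loc[coded.snp_ids]
        chrom_rank = pd.Categorical(
            m["chrom"].astype(str),
            categories=_chrom_order(m["chrom"].astype(str).unique()),
            ordered=True,
        ).codes
        order = np.lexsort((m["pos"].to_numpy(), chrom_rank)).astype(np.int64)
    else:
        order = np.arange(K, dtype=np.int64)

    sigma_a2, s_u2 = derive_prior_scale(config.h2_prior, K, config.pi, Z)
    Zt = np.ascontiguousarray(Z.T)
    is_case = status == 2
    seed = int(config.seed) % (2**31 - 1)

    (
        u_store, incl_count, u_sum, model_size, sigma_tr, mu_tr,
        pct_var, min_case_l, max_ctrl_l, bad_snp,
    ) = _chain_kernel(
        Zt,
        is_case,
        order,
        float(config.pi),
        float(config.nu_u),
        float(s_u2),
        int(config.chain_length),
        int(config.burn_in),
        int(config.window_thin),
        seed,
    )
    if bad_snp >= 0:
        raise FloatingPointError(
            f"non-finite inclusion likelihood ratio at SNP "
            f"{coded.snp_ids[bad_snp]!r}"
        )
    n_kept = config.n_kept
    return ChainPosterior(
        snp_ids=coded.snp_ids,
        model_freq=incl_count / n_kept,
        mean_effect=u_sum / n_kept,
        u_samples=u_store,
        model_size=model_size,
        sigma_u2=sigma_tr,
        mu=mu_tr,
        pct_var_all_snps=float(pct_var),
        prior_sigma_a2=sigma_a2,
        prior_S_u2=s_u2,
        config=config,
        min_case_liability=float(min_case_l),
        max_control_liability=float(max_ctrl_l),
    )


def _chrom_order(labels) -> list[str]:
    """Numeric chromosomes ascending, then others (X, ...) alphabetically."""
    numeric = sorted((l for l in labels if str(l).isdigit()), key=int)
    other = sorted(l for l in labels if not str(l).isdigit())
    return [str(l) for l in numeric] + [str(l) for l in other]
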