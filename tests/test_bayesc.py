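"""Sampler components: prior scale, truncated-normal liabilities, the
SNP inclusion update, the effect-variance update, and whole-chain
properties (determinism, permutation equivariance, sign flip, liability
constraint)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bayesct.bayesc import (
    BayesCConfig,
    derive_prior_scale,
    gibbs_update_snp,
    run_chain,
    sample_liabilities,
    update_sigma_u2,
)
from bayesct.qc import encode_genotypes, filter_snps
from bayesct.simulate import SimulationConfig, simulate_population
from conftest import SMALL_GENOME, toy_genotypes, toy_map


class TestPriorScale:
    def test_h2_half_gives_unit_additive_variance(self):
        Z = np.random.default_rng(0).choice([-10.0, 0.0, 10.0], (50, 10))
        sigma_a2, _ = derive_prior_scale(0.5, 10, 0.999, Z)
        assert sigma_a2 == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        # sigma_a2 = 1, K = 1000, pi = 0.999, vbar = 0.5 -> S = 1/(1*0.5) = 2
        # two animals at +-sqrt(0.5): population column variance = 0.5
        Z = np.vstack(
            [np.full(1000, -np.sqrt(0.5)), np.full(1000, np.sqrt(0.5))]
        )
        sigma_a2, s_u2 = derive_prior_scale(0.5, 1000, 0.999, Z)
        assert s_u2 == pytest.approx(2.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(1)
        Z = rng.choice([-10.0, 0.0, 10.0], (100, 4000))
        h2, pi = 0.24, 0.999
        sigma_a2, s_u2 = derive_prior_scale(h2, 4000, pi, Z)
        vbar = Z.var(axis=0).mean()
        expect = (h2 / (1 - h2)) / (4000 * (1 - pi) * vbar)
        assert s_u2 == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("h2", [0.0, 1.0])
    def test_degenerate_heritability_rejected(self, h2):
        with pytest.raises(ValueError):
            derive_prior_scale(h2, 10, 0.999, np.ones((2, 10)))


def truncated_mean_above_zero(eta: float) -> float:
    """Analytic mean of N(eta,1) truncated to (0, inf)."""
    a = -eta
    return eta + stats.norm.pdf(a) / stats.norm.sf(a)


class TestLiabilities:
    def test_case_at_threshold_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_liabilities(
            np.full(10_000, 2), np.zeros(10_000), rng
        )
        assert (draws > 0).all()
        assert draws.mean() == pytest.approx(math.sqrt(2 / math.pi), abs=0.02)

    def test_far_from_threshold_is_untruncated(self):
        rng = np.random.default_rng(1)
        draws = sample_liabilities(
            np.full(10_000, 1), np.full(10_000, -10.0), rng
        )
        # truncation mass < 1e-20: indistinguishable from N(-10, 1)
        assert draws.mean() == pytest.approx(-10.0, abs=0.05)
        assert draws.std() == pytest.approx(1.0, abs=0.05)

    def test_case_deep_in_control_region(self):
        rng = np.random.default_rng(2)
        draws = sample_liabilities(
            np.full(20_000, 2), np.full(20_000, -3.0), rng
        )
        assert (draws > 0).all()
        assert draws.mean() == pytest.approx(
            truncated_mean_above_zero(-3.0), abs=0.05
        )

    def test_controls_nonpositive(self):
        rng = np.random.default_rng(3)
        draws = sample_liabilities(
            np.full(5_000, 1), np.full(5_000, 1.5), rng
        )
        assert (draws <= 0).all()


class TestSnpUpdate:
    def test_zero_signal_inclusion_below_prior(self):
        """At rhs = 0 the integrated likelihood penalizes inclusion by
        sqrt(lam/(C+lam)) < 1, so inclusion probability sits below the
        prior 1 - pi."""
        rng = np.random.default_rng(0)
        n, pi = 400, 0.99
        z = rng.choice([-10.0, 0.0, 10.0], n)
        r = rng.standard_normal(n)
        r -= z * (z @ r) / (z @ z)  # exactly orthogonal
        included = sum(
            gibbs_update_snp(z, r.copy(), 0.0, 0.01, pi, rng)[0]
            for _ in range(2_000)
        )
        assert included / 2_000 < (1 - pi)

    def test_vanishing_effect_variance_restores_prior_rate(self):
        """As sigma_u2 -> 0 the shrinkage penalty vanishes (BF -> 1) and
        the inclusion rate over null redraws approaches the prior."""
        rng = np.random.default_rng(1)
        n, pi = 200, 0.99
        rate = np.mean(
            [
                gibbs_update_snp(
                    rng.choice([-10.0, 0.0, 10.0], n),
                    rng.standard_normal(n),
                    0.0,
                    1e-12,
                    pi,
                    rng,
                )[0]
                for _ in range(50_000)
            ]
        )
        se = math.sqrt((1 - pi) * pi / 50_000)
        assert rate == pytest.approx(1 - pi, abs=3 * se)

    def test_strong_signal_always_included_with_correct_conditional(self):
        rng = np.random.default_rng(2)
        n = 500
        z = rng.choice([-10.0, 10.0], n)
        u_true = 0.5
        draws = []
        for _ in range(4_000):
            r = z * u_true + 0.1 * rng.standard_normal(n)
            delta, u, _ = gibbs_update_snp(z, r, 0.0, 1.0, 0.999, rng)
            assert delta == 1
            draws.append(u)
        c = z @ z
        v1 = c + 1.0
        # conditional sd = 1/sqrt(C + lam); mean ~ u_true
        assert np.mean(draws) == pytest.approx(u_true, abs=0.01)
        assert np.std(draws) == pytest.approx(1 / math.sqrt(v1), rel=0.2)

    def test_pi_one_limit_always_excludes(self):
        rng = np.random.default_rng(3)
        z = rng.choice([-10.0, 10.0], 100)
        r = z * 2.0  # overwhelming signal
        delta, u, _ = gibbs_update_snp(
            z, r, 0.0, 1.0, 1 - 1e-300, rng
        )
        assert (delta, u) == (0, 0.0)

    def test_residual_bookkeeping_roundtrip(self):
        """Excluding a currently included SNP restores its contribution."""
        rng = np.random.default_rng(4)
        z = rng.choice([-10.0, 0.0, 10.0], 50)
        r_full = rng.standard_normal(50)
        u_cur = 0.3
        r = r_full - z * u_cur  # residual with the SNP in the model
        delta, u, r_new = gibbs_update_snp(z, r, u_cur, 1e-30, 1 - 1e-12, rng)
        assert delta == 0
        np.testing.assert_allclose(r_new, r_full, atol=1e-12)


class TestSigmaUpdate:
    def test_prior_draw_mean(self):
        # m = 0: scaled-inv-chi2(nu, S) has mean nu*S/(nu-2) = 2S at nu = 4
        rng = np.random.default_rng(0)
        s = 3.0
        draws = [
            update_sigma_u2(np.zeros(5), np.zeros(5), 4.0, s, rng)
            for _ in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(2 * s, rel=0.03)

    def test_conjugate_fixed_point(self):
        """A single included effect with u^2 = S_u2 leaves the posterior
        scale at S_u2: (nu*S + S)/(nu + 1) = S."""
        rng = np.random.default_rng(1)
        s = 2.0
        u = np.array([math.sqrt(s)])
        draws = [
            update_sigma_u2(u, np.array([1]), 4.0, s, rng)
            for _ in range(20_000)
        ]
        # mean of scaled-inv-chi2(5, S) = 5*S/3
        assert np.mean(draws) == pytest.approx(5 * s / 3, rel=0.03)

    def test_large_df_degenerates_at_scale(self):
        rng = np.random.default_rng(2)
        s = 1.7
        draws = [
            update_sigma_u2(np.zeros(1), np.zeros(1), 1e6, s, rng)
            for _ in range(200)
        ]
        assert np.mean(draws) == pytest.approx(s, rel=0.01)
        assert np.std(draws) < 0.01


def _small_cohort(seed=0, h2=0.24, qtl=None, n_snps=400, n_sires=40):
    config = SimulationConfig(
        n_sires=n_sires,
        offspring_per_sire=5,
        n_snps=n_snps,
        chromosomes=SMALL_GENOME,
        h2_liability=h2,
        qtl_spec=qtl or [],
        seed=seed,
    )
    gm, smap, pheno, truth = simulate_population(config)
    gm, smap, _ = filter_snps(gm, smap)
    return encode_genotypes(gm), smap, pheno["status"].to_numpy(), truth


class TestRunChain:
    def test_invalid_chain_lengths_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            BayesCConfig(chain_length=100, burn_in=100)

    def test_deterministic_given_seed(self):
        coded, smap, status, _ = _small_cohort(seed=5)
        cfg = BayesCConfig(chain_length=400, burn_in=100, window_thin=10, seed=9)
        a = run_chain(coded, status, cfg, smap)
        b = run_chain(coded, status, cfg, smap)
        np.testing.assert_array_equal(a.model_freq, b.model_freq)
        np.testing.assert_array_equal(a.u_samples, b.u_samples)
        np.testing.assert_array_equal(a.sigma_u2, b.sigma_u2)
        assert a.pct_var_all_snps == b.pct_var_all_snps

    def test_liability_constraint_every_iteration(self):
        coded, smap, status, _ = _small_cohort(seed=6)
        cfg = BayesCConfig(chain_length=300, burn_in=50, window_thin=10, seed=1)
        post = run_chain(coded, status, cfg, smap)
        assert post.min_case_liability > 0
        assert post.max_control_liability <= 0

    def test_thinned_sample_count(self):
        coded, smap, status, _ = _small_cohort(seed=7)
        cfg = BayesCConfig(chain_length=430, burn_in=100, window_thin=25, seed=1)
        post = run_chain(coded, status, cfg, smap)
        assert post.u_samples.shape == (330 // 25, coded.n_snps)

    def test_permutation_equivariance_bitwise(self):
        """The sampler visits SNPs in genome map order, so permuting the
        storage order of columns leaves every posterior summary
        bit-identical (after unpermuting)."""
        coded, smap, status, _ = _small_cohort(seed=8)
        cfg = BayesCConfig(chain_length=300, burn_in=100, window_thin=20, seed=4)
        base = run_chain(coded, status, cfg, smap)
        rng = np.random.default_rng(0)
        perm = rng.permutation(coded.n_snps)
        from bayesct.qc import CodedMatrix

        shuffled = CodedMatrix(
            coded.animal_ids, coded.snp_ids[perm], coded.Z[:, perm],
            coded.p[perm],
        )
        out = run_chain(shuffled, status, cfg, smap)
        freq = pd.Series(out.model_freq, index=out.snp_ids)
        np.testing.assert_array_equal(
            freq.loc[base.snp_ids].to_numpy(), base.model_freq
        )

    def test_sign_flip_statistical_equivariance(self):
        """Flipping one SNP's allele coding (z -> -z) flips its posterior
        mean effect and leaves its model frequency statistically
        unchanged."""
        coded, smap, status, truth = _small_cohort(
            seed=9, qtl=[("1", 10, 0.20)], n_snps=300
        )
        j = int(np.flatnonzero(coded.snp_ids == truth["qtl_windows"][0]["snps"][0])[0])
        cfg = BayesCConfig(chain_length=3000, burn_in=500, window_thin=50, seed=2)
        base = run_chain(coded, status, cfg, smap)
        from bayesct.qc import CodedMatrix

        Zf = coded.Z.copy()
        Zf[:, j] = -Zf[:, j]
        flipped = run_chain(
            CodedMatrix(coded.animal_ids, coded.snp_ids, Zf, coded.p),
            status, cfg, smap,
        )
        assert base.model_freq[j] > 0.2  # the planted SNP is visible
        assert abs(base.model_freq[j] - flipped.model_freq[j]) < 0.15
        assert np.sign(base.mean_effect[j]) == -np.sign(flipped.mean_effect[j])

    def test_null_chain_stays_sparse(self):
        """On signal-free data the model stays near its prior sparsity:
        mean model size within a factor ~2 of K(1-pi), and no SNP
        accumulates a large model frequency over a long chain (sticky
        data-augmentation episodes decay with chain length)."""
        coded, smap, status, _ = _small_cohort(
            seed=0, h2=0.0, n_snps=1000, n_sires=40
        )
        cfg = BayesCConfig(
            chain_length=55_000, burn_in=5_000, window_thin=100, seed=200
        )
        post = run_chain(coded, status, cfg, smap)
        prior_size = coded.n_snps * (1 - cfg.pi)
        mean_size = post.model_size[cfg.burn_in:].mean()
        assert 0.2 * prior_size < mean_size < 1.5 * prior_size
        assert post.model_freq.max() < 0.15

    def test_unknown_status_animals_excluded(self):
        coded, smap, status, _ = _small_cohort(seed=10)
        status = status.copy()
        status[:5] = 0  # unknown
        cfg = BayesCConfig(chain_length=200, burn_in=50, window_thin=10, seed=3)
        post = run_chain(coded, status, cfg, smap)  # runs on the 195 others
        assert post.model_size.shape == (200,)
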