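# Methods

## The problem

`bayesct` implements a genome-wide association analysis for a binary
trait collected under a matched case–control design, the setting of
equine insect bite hypersensitivity (IBH) studies: two cohorts of a few
hundred horses, genotyped on a dense SNP chip, with controls matched to
cases on sire, premise, coat colour, withers height, sex, import status,
age and scoring date. Because the trait is binary and the cohorts are
small and family-structured, the analysis rests on three components:

1. a **probit liability threshold model** linking case status to a
   latent Gaussian liability,
2. **Bayes-C** Bayesian variable selection fitting all SNPs
   simultaneously with a sparse mixture prior, and
3. a **1 Mb window variance partition** of the posterior, which
   aggregates the effects of adjacent SNPs in linkage disequilibrium
   with the same QTL.

## Model

For animal *i* with genotype covariates *z*<sub>ij</sub> the linear
predictor is

  η<sub>i</sub> = μ + Σ<sub>j</sub> z<sub>ij</sub> u<sub>j</sub> δ<sub>j</sub>

and the latent liability is l<sub>i</sub> = η<sub>i</sub> + e<sub>i</sub>,
e<sub>i</sub> ~ N(0, 1). The residual variance is not identifiable on
the liability scale and is fixed at 1; the threshold sits at 0 and μ
absorbs prevalence. Cases have l > 0, controls l ≤ 0.

Genotypes enter as AA = −10, AB = 0, BB = +10, with missing calls
imputed to the SNP's observed mean coded value. No further centring is
applied; μ absorbs the non-zero column means.

Each SNP effect u<sub>j</sub> is zero with prior probability π (the
indicator δ<sub>j</sub>) and N(0, σ<sub>u</sub>²) otherwise, with one
common variance σ<sub>u</sub>² ~ scaled-inv-χ²(ν<sub>u</sub>,
S<sub>u</sub>²). Defaults: π = 0.999, ν<sub>u</sub> = 4,
chain 200,000 iterations with 20,000 burn-in, effect vectors stored
every 100th post-burn-in iteration. π = 0.999 keeps roughly K(1−π)
SNPs in the model per iteration — fewer than animals, limiting
overfitting.

**Prior scale.** With the residual fixed at 1, a liability heritability
h² implies an additive variance σ<sub>a</sub>² = h²/(1−h²). The scale
parameter spreads it over the expected model size:
S<sub>u</sub>² = σ<sub>a</sub>²/(K(1−π)·v̄), where v̄ is the mean
per-SNP covariate variance. On allele-content coding v̄ equals
2p̄q̄; using the empirical covariate variance makes the implied
genetic variance invariant to the ±10 coding scale. The default prior
heritability is 0.24, a pedigree-based estimate for IBH on the
liability scale.

**Gibbs cycle** (fixed order, for reproducibility): liabilities
(one-sided truncated normals around η, far-tail draws by Robert's
exponential-rejection sampler) → μ (flat prior, conditional normal) →
each SNP in genome map order → σ<sub>u</sub>². The SNP update samples
δ<sub>j</sub> from its marginal with u<sub>j</sub> integrated out —
odds = ((1−π)/π)·√(λ/(C<sub>j</sub>+λ))·exp(r²/(2(C<sub>j</sub>+λ)))
with λ = 1/σ<sub>u</sub>², C<sub>j</sub> = z<sub>j</sub>'z<sub>j</sub>
and r the full-conditional right-hand side — then u<sub>j</sub> from
its conditional normal when included. Residuals are updated in place,
so one iteration costs O(nK). The hot loop is a numba kernel driven by
a single RandomState seeded per chain: results are bit-reproducible
given the seed, and permuting SNP storage order leaves them
bit-identical because SNPs are always visited in map order.

**Reported summaries**: per-SNP model frequency (share of post-burn-in
iterations with δ<sub>j</sub> = 1; a proportion in [0, 1]) and posterior
mean effect; per-iteration model size, σ<sub>u</sub>² and μ; thinned
effect vectors; and the % of variance by all SNPs, the posterior mean of
100·var(g)/(var(g)+1) with g = Zu the genomic values.

## Window variance partition

SNPs map to consecutive non-overlapping 1 Mb windows,
window = (chromosome, floor(bp/10⁶)). For every thinned effect sample
the windowed genomic values g<sub>w</sub> = Z<sub>w</sub>u<sub>w</sub>
are computed and the window share is
100·var<sub>i</sub>(g<sub>w</sub>)/var<sub>i</sub>(g<sub>total</sub>).
The denominator is the variance among individuals of the total genomic
value — not the sum of per-SNP variances — so a single-window genome
scores exactly 100% and the infinitesimal threshold logic is coherent.
Posterior means average over all thinned samples, zeros from
excluded-window iterations included; exceedance is the fraction of
samples above the infinitesimal threshold 100/N % (N windows; 2,376
windows round the threshold to 0.04%). N defaults to the count of
SNP-bearing windows; the genome-length convention (sum of ceil(Mb) per
chromosome) is also computable. Adjacent windows can be merged; per
sample var(g<sub>a</sub>+g<sub>b</sub>) = var(g<sub>a</sub>) +
var(g<sub>b</sub>) + 2cov(g<sub>a</sub>,g<sub>b</sub>) holds exactly,
so merged shares exceed the component sum exactly when the windows'
genomic values covary positively.

Variances among individuals use the sample variance (ddof = 1)
consistently; the window shares are invariant to that choice.

## Stratification diagnostics

Genomic kinship uses identity-by-state on genotypes coded {0, ½, 1}:
f<sub>ij</sub> = mean over jointly-observed autosomal polymorphic SNPs of
(x<sub>ik</sub>−p<sub>k</sub>)(x<sub>jk</sub>−p<sub>k</sub>)/(p<sub>k</sub>(1−p<sub>k</sub>)).
The mean (rather than raw sum) keeps the statistic independent of panel
size; classical MDS is invariant to this scaling. The distance transform
is d = max(f) − f with zero diagonal — any decreasing affine transform
yields the same principal coordinates after double centring — followed
by classical multidimensional scaling (−½ J d² J eigendecomposition,
negative eigenvalues truncated, numerically-zero eigenvalues collapsed
to exact zeros). The matching-factor screen fits binomial GLMs with
logit link (univariable per factor and one joint model) and reports
joint Wald p-values per term; perfectly separating factors are reported
non-estimable rather than raising. Exclusion by factor level (e.g.
removing imported animals) reports case/control counts before and
after.

## Quality control

SNPs are removed when call-rate < 0.90 (strict) or minor allele
frequency ≤ 0.02 (inclusive); both boundaries are unit-tested. QC is
applied per cohort. Animal call-rate (> 0.90) is checked once, before
SNP filtering. No Hardy–Weinberg filter, LD pruning or strand flipping.

## The synthetic cohort generator

The generator emulates the study design rather than any particular real
dataset: paternal half-sib families (default 40 sires × 5 offspring;
one unique dam per offspring), founder B-allele frequencies uniform on
(0.05, 0.95), genotypes by gamete transmission from founder haplotypes,
a genome of 31 autosomes plus X totalling 2,376 Mb, ~50% case
prevalence by thresholding the liability at its empirical quantile
(mimicking recruitment to a target), liability heritability 0.24, and a
matching-factor table drawn independently of liability (so the logistic
screen is null-calibrated). A confounder mode ties import status to
case odds (≈ OR 8 at 13% import frequency) to exercise the exclusion
path. QTL windows receive their stated share of liability variance on
the SNP(s) nearest the window centre; the remainder of h² is an
infinitesimal background over all other SNPs. Component effects are
rescaled empirically so realized variance fractions match their
targets.

Founder haplotypes are site-independent by default — the null case
stays analytically checkable — with an optional block-LD mode (blocks
of 20 SNPs sharing a latent uniform) for window-level tests; 20 is a
free parameter, not an estimate of real LD decay. The generator does
not simulate X-linked dosage (X is treated as diploid autosomal, which
matches an all-mares cohort), insect exposure, age at onset, or
questionnaire phenotypes.

What passing tests on this generator do **not** show about real data:
there is no background LD by default, no genotyping batch structure, no
assortative mating, and matching is simulated as perfect; real-data
model frequencies and window percentages will be flatter and more
LD-smeared than synthetic ones.

## Problem sizes and numerical choices

Test-suite and acceptance runs use reduced chains sized so the full
suite completes on one CPU: the full-panel calibration uses 46,888 SNPs
× 200 animals with 500 burn-in + 2,000 (tests) or 2,000 + 4,000
(acceptance script) iterations; recovery and null studies use 2,000 to
5,000 SNPs with 1,800–2,500 iterations. 0/0 window shares (empty
model) are defined as 0. Inclusion log-odds are clamped at ±35 before
exponentiation; a non-finite log-odds aborts with the SNP id. σ<sub>u</sub>²
is initialised at its prior mean, liabilities at ±0.8.

## Known limitations

- **Sticky-SNP mixing.** The single-site Gibbs update with liability
  augmentation mixes slowly once a SNP with a sizeable effect enters
  the model: liabilities adapt to the fitted effect, which sustains it.
  On null data the maximum per-SNP model frequency decays with chain
  length (≈0.4 at 2k iterations, ≈0.09 at 50k, K = 1,000) but short
  chains overstate individual model frequencies, and null window
  percentages are heavy-tailed at desk scale: a sticky SNP's window can
  average far above the infinitesimal expectation. Production analyses
  should use full-length chains (200k iterations) as the defaults do.
- **Model size under null data** sits some 10–25% below the prior
  expectation K(1−π): null data carry less signal than the prior
  predictive, and the inclusion Bayes factor is heavy-tailed.
- **SNP-based variance capture is slot-limited.** With π = 0.999 the
  model holds ~K(1−π) SNPs; at small K the infinitesimal fraction of
  heritability is structurally uncapturable and the total %-variance
  estimate sits below the simulated h² (e.g. ~14% of a true 24% at
  K = 5,000, n = 400, against ~26% at K = 46,888, n = 200). The same
  gap between SNP-based and pedigree heritability appears in real
  analyses of this design.
- Perfectly separating matching factors (small cohorts, rare levels)
  make the Wald screen non-estimable; those are reported, not tested.
- Model frequencies are reported strictly as proportions in [0, 1];
  published tables of this design sometimes print window-top SNP
  "model frequency" values above 1, which this package does not
  emulate.
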