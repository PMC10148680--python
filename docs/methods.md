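# Methods

## Phenotype model and the covariance signature of a POE

At a biallelic SNP with alternative allele B, let `beta_M` and `beta_P` be
the K-vectors of effects of a maternally vs paternally inherited B allele
on K continuous traits (already adjusted for confounders). With trait
errors `eps ~ (0, Sigma)` shared by all genotype groups:

* AA homozygotes: `y = mu + eps`
* BB homozygotes: `y = mu + beta_M + beta_P + eps`
* AB heterozygotes: `y = mu + pi*beta_M + (1-pi)*beta_P + eps`, where
  `pi ~ Bernoulli(1/2)` indicates a maternal-origin B allele.

Both homozygous groups have covariance `Sigma_hom = Sigma`; heterozygotes,
being a balanced mixture of the two origin states, have

    Sigma_het = Sigma_hom + (1/4) b b',   b = beta_M - beta_P,

so `Sigma_het = Sigma_hom` iff no trait has a POE. A marginal association
(`beta_M = beta_P != 0`) shifts group means but no covariance, and is
removed by the per-genotype median centering below.

## The robust covariance-equality test

Box's M — the textbook test for covariance equality — is notoriously
sensitive to non-normality, so the test is built instead from robust
location-free features. After median-centering each trait within each
genotype group (AA, AB, BB):

1. Pool subjects into heterozygotes and homozygotes. Within each pooled
   group recompute per-trait medians `M_k` (a no-op up to ties within the
   heterozygote group; material for the pooled homozygotes).
2. For each subject and ordered trait pair (k <= k'), set
   `Z = (x_k - M_k)(x_k' - M_k')` and `W = sign(Z) * sqrt(|Z|)`, with
   `W = 0` at `Z = 0` (the unique continuous extension of `Z/|Z|^{1/2}`).
   The group mean of W is a robust, square-root-compressed summary of the
   (co)variance for that pair.
3. Compare the two groups' p = K(K+1)/2 feature-mean vectors with the
   two-sample Hotelling T²,
   `t² = (n1 n2/(n1+n2)) d' S^{-1} d`, `S` the pooled covariance
   (denominator n1+n2-2), and refer
   `F = (n1+n2-p-1)/(p(n1+n2-2)) t²` to `F(p, n1+n2-p-1)` — the exact null
   law under normal W, used as an approximation otherwise.

Pair ordering is fixed (row-major upper triangle including the diagonal:
(1,1),(1,2),...,(1,K),(2,2),...,(K,K)) so outputs are reproducible.

The post hoc interaction test is the identical machinery with groups
AA vs BB. A gene–gene or gene–environment interaction makes the two
homozygote covariances differ, while a pure POE leaves them equal, so on
variants already flagged by the main test it separates the two
explanations. The intended genome-scan usage is two-stage: Bonferroni
screen with the main test, then the post hoc test on the hits with its
own Bonferroni cutoff (alpha over the number of hits).

### Degenerate inputs and numerical choices

* Even-sized groups use the midpoint median (numpy convention).
* A singular pooled feature covariance is reported as `status="singular"`
  and the variant excluded; a silent pseudo-inverse would change the null
  distribution. Singularity occurs for discretized traits with massive
  ties (many exactly-zero W columns), not for continuous data.
* Group-size guard: each compared group must have at least `p + 2`
  subjects (configurable), guaranteeing positive denominator degrees of
  freedom with margin; smaller groups return `status="insufficient_n"`.
* Rows missing the genotype are dropped for that variant only; phenotypes
  and covariates are required complete globally (complete-case filtering
  before the scan).
* Tie-heavy (coarsely discretized) phenotypes put mass at `Z = 0`; the
  test is defined there (W = 0) but was designed for continuous traits and
  is not optimized for that regime.

The exactness claims worth stating precisely: the test statistic is
invariant to per-trait affine maps `y -> a*y + b` (`a != 0`) and to a
constant shift of any genotype group, both up to floating-point rounding
of order 1e-14 in relative terms (the shifted inputs round differently at
the last bit, so bit-identity holds only in exact arithmetic).

## Univariate comparator

The single-trait competitor tests heterozygote-vs-homozygote variance
inflation per trait with a Brown–Forsythe (median-based Levene) test after
the same per-genotype median centering: absolute deviations from the
comparison group's median are compared by one-way ANOVA with F(1, n-2).
The published description of this comparator does not fully pin down its
internals; this implementation is a faithful two-group Brown–Forsythe
reading of it, with homozygotes pooled after per-genotype centering for
symmetry with the multivariate test. Multi-trait decisions take the
minimum p-value against `alpha/K`, or against `alpha/K_eff` where `K_eff`
is the smallest number of principal components of the trait correlation
matrix explaining at least 90% of total variance (correlation rather than
covariance, so the count is scale-free).

## Simulation design

The generator reproduces the simulation conditions under which the method
was characterized; its defaults are those conditions, not free dials.

* **Genotypes.** Each of n offspring gets two parents with alleles drawn
  `Bernoulli(MAF)` (default MAF 0.25); each parent transmits one allele by
  a fair coin. Offspring genotypes land in Hardy–Weinberg proportions and
  the maternal-origin indicator of each heterozygote is retained as
  generator truth (analyses never see it; the trio benchmark does).
* **Traits.** Intercepts `mu_k ~ N(0,1)` per replicate; unit error
  variances; pairwise correlations drawn per replicate from Uniform(0,0.3)
  / (0.3,0.5) / (0.5,0.7) for low/medium/high levels (redrawn until
  positive definite, up to 100 times, then projected to the nearest PD
  correlation with eigenvalue floor 1e-8 — in practice never needed for
  K <= 10 at these ranges).
* **Effects.** Power settings put a maternal effect of 0.5, 0.6 or 0.75 on
  the first m traits with `beta_P = 0`. The factorial bookkeeping exposed
  by `null_grid()` (27 settings) and `power_grid()` (162 settings) matches
  the study layout.
* **Skewed errors.** The Vale–Maurelli construction: a single Fleishman
  cubic `a + bZ + cZ² + dZ³` (a = -c) applied to correlated standard
  normals, with pairwise intermediate correlations solved from the cubic
  relation `rho_Y = rho(b²+6bd+9d²) + 2rho²c² + 6rho³d²` (Brent's method)
  and the intermediate matrix PD-projected if needed. The solver enforces
  unit variance exactly (b solved from (c,d)) and fits skewness/kurtosis
  by least squares. The nominal marginal targets (skewness 2, excess
  kurtosis 2) lie outside the Fleishman cubic's attainable region — any
  distribution needs excess kurtosis >= skewness² - 2, and the cubic's
  region is strictly inside that bound — so the generator flags the fit
  infeasible and uses the closest attainable marginal (achieved skewness
  ~1.45, excess kurtosis ~2.12, verified by Monte Carlo). Robustness
  results therefore describe "strongly skewed" rather than literally
  (2, 2) errors.
* **Interaction (GxE) cohorts.** A standard-normal covariate with main
  effects 0.3–0.7 on designated traits plus a centered-genotype x
  covariate interaction scaled analytically — using Var(g) = 2*MAF*(1-MAF)
  and unit covariate variance — so the interaction explains a requested
  fraction (0.005–0.01) of total trait variance.
* **Reproducibility.** Every study driver derives one child RNG per
  replicate from a SeedSequence of the scenario seed, and each replicate
  consumes its stream in a fixed order (Sigma, mu, genotypes, errors) that
  does not depend on the effect vectors. Two scenarios differing only in
  effects therefore share every random draw — which is what makes the
  marginal-effect equivalence above testable at machine precision.

### Study drivers and problem sizes

Monte-Carlo drivers report rejection frequencies with binomial standard
errors at levels {0.05, 0.005, 5e-4, 5e-5} (null) and {0.005, 5e-4}
(power). The shipped tests and the acceptance script run reduced
replicate counts — 2000 for null calibration, 1000/600 for power
orderings, 500 for post hoc discrimination, 400–500 per power point for
the sample-size bisection — chosen so each assertion has adequate
Monte-Carlo resolution for the margin it checks while the whole suite
stays fast.

The trio benchmark analyses only heterozygous offspring, grouped by true
parental origin, via two-group MANOVA on raw traits (algebraically
Hotelling's T² with the exact F transform). `relative_efficiency` bisects
each method's Monte-Carlo power curve over the total number of simulated
offspring to the smallest n reaching the target power (default 0.8 at
alpha = 5e-4) and returns the ratio. At the default design (2 of 3 traits
with maternal effect 0.75, medium correlation, MAF 0.25) the measured
ratio is ~18x, varying roughly as 1/b² in the effect size b, and
stable across K and correlation levels; mean-based family designs are an
order of magnitude more sample-efficient whenever parental origin is
actually observed.

## What the synthetic cohorts do and do not emulate

They emulate: Hardy–Weinberg genotypes from random mating, equal-variance
correlated trait errors (normal or strongly skewed), fixed parental
effects, unmeasured-covariate interactions of controlled strength. They do
not emulate: linkage disequilibrium between variants, population
stratification or relatedness, genotyping error, trait missingness,
maternal-genotype or other trans-generational effects, binary traits, or
ascertainment. Passing tests demonstrate the statistical properties of the
test under its own model; on real cohorts, covariate residualization must
carry the burden of confounder control, and interaction-driven false
positives are only screened — not eliminated — by the post hoc test.

## Calibration notes

With normal traits the null distribution of p-values is uniform to
Monte-Carlo resolution (at 10000 replicates: empirical rate 0.048 at
alpha = 0.05, KS p = 0.79). Under the strongly skewed error model the test
is measurably but mildly anti-conservative: about 0.059 at nominal 0.05
for K=3, n=5000, shrinking slowly with n (0.061 at n=1000, 0.057 at
n=20000) and growing with K — at K=10 the deviation from uniformity is
clear at 2000 replicates. Practitioners testing many highly skewed traits
should expect slight inflation and may prefer rank-based preprocessing.

## Known limitations

* The F reference law is exact only for normal W features; heavy-tailed
  traits induce the slight finite-sample inflation quantified above.
* The univariate comparator is a reconstruction from its published
  description, not a port of the original software.
* Covariance-based POE detection cannot distinguish a POE from phenomena
  producing the same covariance signature at a single locus beyond what
  the AA-vs-BB post hoc test can separate.
* Continuous traits only; binary/ordinal outcomes need a liability-style
  extension that is out of scope here.
* The genome scan treats variants independently (no LD-aware thresholding
  beyond Bonferroni).
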