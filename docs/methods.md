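# Methods

## Model

The package treats a binary GWAS phenotype Y as a noisy observation of a
latent true phenotype Y′. Two layers:

1. **Genetic layer (probit mixed model).** Pr(Y′_i = 1 | β, u) =
   Φ(X_i β + u_i), where X is the n × m matrix of allele counts over the
   *training SNPs* (the SNPs whose association p-value with the observed
   phenotype passes the filter p), β their effects, and u ~ MVN(0, σ_u² A)
   polygenic random effects over the genomic relatedness matrix A. The
   unit-variance liability noise is absorbed by the probit CDF; no separate
   noise parameter is carried.
2. **Label layer.** α = P(Y=1 | Y′=1) (true-positive probability) and
   λ = P(Y=1 | Y′=0) (false-positive probability). Marginalising Y′ gives a
   per-sample two-component mixture likelihood; Bayes' rule on the (Y′, Y)
   joint gives the misclassification posteriors used to mark samples.

Priors: α ~ Beta(10, 1) (informative: most recorded cases are genuine),
λ ~ Beta(1, 1) (flat), β_j ~ N(0, 1), σ_u² flat on (0, σ_u²max] with
σ_u²max = 100. The mixture has a label-switching mirror mode (α and λ roles
exchanged); the Beta(10, 1) prior orients the posterior, and iterations with
α < λ are discarded from misclassification averaging. A chain losing more
than half of its post-burn-in iterations to the switched mode is flagged
unusable and the pipeline starts replacement chains (the multi-chain
policy); chains are additionally screened by the Geweke diagnostic
(|z| < 1.96 on α, λ, σ_u²).

## Sampler

Per iteration, in order:

1. joint Metropolis–Hastings proposal for (α, λ, β): truncated normals on
   (0, 1) for α and λ (with the Hastings correction for the centre-dependent
   truncation constant — the correction is included because omitting it
   biases the stationary distribution near the boundaries), independent
   normals for β; one acceptance ratio for the whole block using the
   observed-data likelihood times the (α, λ, β) priors;
2. Bernoulli misclassification indicators from the label posteriors; marked
   samples flip their working latent label for this iteration;
3. latent liabilities l_i ~ N(X_i β + u_i, 1) truncated to (0, ∞) for latent
   cases and (−∞, 0] for latent controls (the standard truncated-normal data
   augmentation for probit models), drawn by inverse CDF in log space
   (`ndtri_exp`) so means deep inside the rejected tail are exact and never
   loop;
4. a sequential single-site Gibbs scan for u: u_i ~ N(û_i, (1 + c_ii γ)⁻¹),
   û_i = (1 + c_ii γ)⁻¹((l_i − X_i β) − γ c_{i,−i} u_{−i}), with c the
   entries of A⁻¹ and γ = 1/σ_u² (compiled with numba; the n² inner products
   dominate the per-iteration cost);
5. σ_u² from its flat-prior conditional ∝ (σ_u²)^{−n/2} exp(−u'A⁻¹u / 2σ_u²)
   on (0, 100], an inverse-gamma(n/2 − 1, u'A⁻¹u/2) truncated above, sampled
   by inverse CDF via the regularised incomplete gamma; the exponent uses
   q = n, the dimension of u.

Initial state: α, λ, β drawn from their priors, u = 0, σ_u² = 0.1. Proposal
scales adapt multiplicatively, scale ← scale·exp(κ(rate − 0.2)) with gain
κ = 1/batch, every 100 iterations during burn-in only, so adaptation is
diminishing and frozen afterwards (ergodicity is preserved). Defaults are
100,000 iterations with 20,000 burn-in at full scale; the desk preset uses
10,000/2,000.

Averages: a sample's misclassification probability is the number of
iterations it was marked divided by the number of retained (post-burn-in,
non-switched) iterations. With several usable chains the per-sample
probabilities are averaged across chains. The threshold t is a percentile
(default 99; real-data mode 95 over 10 runs) of the probabilities among
*cases*; flagged cases (strictly above t) are switched to controls. Only
cases are ever switched: the pipeline targets differential misclassification
where controls leak into the case set.

## Association stage

Binary phenotypes are analysed on the quantitative scale with a linear mixed
model: the GRM A = ZZ'/m* over MAF > 5% SNPs (Z column-standardised), the
variance-component ratio δ = σ_e²/σ_g² fitted once on the null model by REML
over the eigenbasis of A, then each SNP Wald-tested in the whitened
coordinates. The residual variance is re-estimated per SNP, and the
reference distribution is Student-t with the per-model residual degrees of
freedom rather than the normal: this makes the A = I path *exactly* ordinary
least squares (the equivalence is tested against statsmodels OLS), and at
GWAS sample sizes the two references are numerically indistinguishable.
Benjamini–Hochberg adjustment is delegated to statsmodels and cross-checked
against a hand-rolled step-up in the tests. Training SNPs are those with
unadjusted p below the filter (Bonferroni α/m by default; 10⁻⁵ heuristic in
real-data mode; {10⁻⁴, 10⁻⁵, 10⁻⁶·³} as the sweep). LD pruning is greedy
within 50 kb windows advancing 5 SNPs at a time, removing the lower-MAF
member of any pair with r² > 0.20 (position breaks ties — the upstream SNP
is kept). Discoveries after correction: non-training SNPs with max r² below
k = 10⁻² against every training SNP, BH-adjusted p < 0.1 with the corrected
phenotype and not with the original.

## Simulator

Two designs:

* **Strategy 1 (structure-free):** MAF drawn uniformly from {0.1, 0.2, 0.4},
  genotypes i.i.d. Binomial(2, f) (Hardy–Weinberg, no LD), 30 causal SNPs
  with β ~ N(2, 0.3), liability L = Xβ + ε thresholded at its median for a
  balanced case/control split. The median split (rather than a fixed zero
  threshold) is used because with mean-2 effects and no intercept a zero
  threshold cannot produce balance.
* **Strategy 2 (structured, the default):** MAF ~ Uniform(0, 0.5), 300 of
  100,000 SNPs causal with β_j ~ N(0, σ_g²[2f_j(1−f_j)]^a), σ_g² = 0.1,
  a = −0.38 (rarer variants get larger effects), u ~ MVN(0, 2·A) with A the
  GRM of the simulated genotypes (MAF > 5%), prevalence drawn uniformly from
  (0.1, 0.5) and imposed by the empirical liability quantile, then a
  1000-case / 3000-control study sampled from the 10,000-sample population.
  Raw allele counts (not standardised genotypes) enter Xβ.

One genotype pool and one random-effects vector are shared across all
replicates of a study; each replicate redraws effect sizes, prevalence,
liability noise, the case/control sample, and the label flips. Differential
misclassification flips exactly round(fraction · #controls) randomly chosen
controls to cases and records the flipped set as ground truth. **Every
misclassification rate in a study is applied to the same per-replicate true
phenotype** (a paired design), so cross-rate comparisons are not confounded
by replicate-level variability.

Realized heritability is reported under two numerators (SNP-only and
SNP + u) because the two definitions differ substantially when σ_u² = 2;
output labels state which is which, and neither is claimed to be *the*
heritability of the liability.

What the simulator does not emulate: LD between SNPs, covariate effects
(age/sex), non-random (genetically correlated) misclassification,
case-enriched ascertainment beyond the fixed 1:3 sampling, genotyping error
or missingness. Passing benchmarks therefore show correctness of the
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Desk-scale preset

The full design (100 replicates, n = 4000, m = 100,000, 10⁵ MCMC iterations)
is cluster-scale. The desk preset runs in minutes: 5 replicates, an
800-sample study (200 cases / 600 controls from a 2000-sample population),
m = 10,000 with 30 causal SNPs, rates {3, 5, 10}%, 10,000 iterations with
2,000 burn-in. Two compensating choices keep the training SNPs as
informative as at full scale, since per-SNP association power scales with
n × variance explained: the effect-variance scale is raised by the same
factor the sample count shrank (σ_g² 0.1 → 0.5), and the training filter is
p < 10⁻⁴ (one member of the standard filter sweep) instead of Bonferroni,
which has little power at n = 800. With these choices the desk benchmark
reproduces the full design's qualitative shape: detection ROC roughly flat
in the misclassification rate, detection PR rising with it.

## Numerical choices

* σ_i is clipped to [10⁻¹⁰, 1 − 10⁻¹⁰] before logs and odds ratios.
* A receives diagonal jitter 10⁻⁶ · mean(diag) before Cholesky/inversion.
* An intercept column is prepended to the training design by default (the
  1:3 case/control ratio is incompatible with a zero-intercept probit); its
  coefficient shares the N(0, 1) prior. `strict_paper_mode` disables it.
* Genotypes enter the misclassification model as raw 0/1/2 counts; a config
  option centres columns.
* The Geweke spectral density at zero uses a Yule–Walker AR fit (order
  ≤ 10); degenerate zero-variance segments return ±∞ and flag the chain.
* u'A⁻¹u = 0 (all-zero u, e.g. immediately after initialisation) leaves
  σ_u² unchanged instead of sampling from a degenerate density.
* n ≤ 2 makes the σ_u² conditional non-inverse-gamma-normalisable; a
  numeric inverse-CDF on a log grid covers that corner.
* Equal detection scores collapse to one ROC/PR operating point; mean curves
  interpolate onto a fixed 201-point grid.
* Seeds: one master `SeedSequence` split into per-replicate and per-chain
  streams; identical seeds give bit-identical results.

## Ablations

`disable_mixed_model` fixes u = 0 and skips the σ_u² update (the
misclassification layer over a fixed-effects probit); `disable_adaptation`
freezes the proposal scales. These are approximations for comparison
purposes, not reproductions of any published alternative sampler.

## Known limitations

* The label layer models both α and λ but the pipeline only corrects cases
  to controls; control-to-case correction would require flagging controls.
* EMMAX-style per-SNP tests with variance components fixed from the null
  model understate uncertainty for very strong SNPs; an exact per-SNP REML
  is not implemented.
* The percentile threshold t guarantees a fixed flag fraction rather than a
  false-discovery guarantee; conservative t is the intended usage.
* Chains can stick in the label-switched mode for the whole run (more often
  on weak training sets); they are detected and replaced, but hard problems
  may need many chains.
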