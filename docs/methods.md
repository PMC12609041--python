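# Methods

## The model

`priorgs` analyses a quantitative trait measured repeatedly on genotyped
individuals with the repeatability animal model

    y = Xb + Zu + Wp + e
    u ~ N(0, K σ²_a),   p ~ N(0, I σ²_pe),   e ~ N(0, I σ²_e)

where `y` stacks all records, `X` carries the categorical fixed factors
(measurement year, herd, sex, age; reference-coded with an intercept),
`Z = W` maps records to individuals, `u` is the additive genetic effect with
a genomic covariance `K`, and `p` the permanent environmental effect that
makes records of the same animal more alike than their genetics alone
would. Heritability is `h² = σ²_a / (σ²_a + σ²_pe + σ²_e)` and repeatability
`rep = (σ²_a + σ²_pe) / (σ²_a + σ²_pe + σ²_e)`; repeatability upper-bounds
heritability.

`K` is a VanRaden method-1 genomic relationship matrix,
`G = ZZᵀ / 2Σpᵢ(1−pᵢ)` with `Z` the dosage matrix centered at twice the
observed sample allele frequencies. The package's contribution is the
trait-specific weighted kinship: markers are partitioned by GWAS rank into a
top-k% prior set (matrix `G₁`) and the remainder (`G₂`), each subset's
additive variance `σ²_G1`, `σ²_G2` is estimated by its own REML fit, and

    G_t = ω G₁ + (1 − ω) G₂,    ω = σ²_G1 / (σ²_G1 + σ²_G2).

Subset variances come from *separate* single-kinship fits by default. A
joint two-random-effect fit is available (`mode="joint"`), but when the two
matrices overlap strongly only the sum of the two variances is well
identified, and the separate-fit arithmetic is what the weight definition
above assumes.

## GWAS and prior-set selection

The scan is an iterative fixed-effect GWAS in the BLINK style. Each round
regresses the adjusted phenotype on `[intercept, pseudo-QTN dosages,
SNP dosage]` by OLS for every SNP (a pseudo-QTN is itself tested against the
remaining covariates); candidates are then reselected: SNPs in ascending
p-value order are greedily retained while their squared dosage correlation
with every retained candidate stays below `ld_r2_max` (default 0.7, cap 20),
and the retained prefix length t is chosen by an information criterion over
refits of the phenotype on the first t candidates. Iteration stops when the
pseudo-QTN set is stable or after `max_iterations` (default 10).

The criterion defaults to `-2·LL + 2·K·ln(n)` (`bic_penalty_form="doubled"`,
K = number of pseudo-QTNs); the conventional `-2·LL + K·ln(n)` is available
as `"standard"`. The doubled penalty is deliberately conservative — under a
null scan of m markers the best candidate's chi-square is of order `2 ln m`,
which the doubled penalty rejects for the panel sizes used here.

Top-k% prior sets are the `floor(k·m)` smallest-p markers of the final
conditioned scan, with p-value ties broken by genome position so selection
is deterministic. Population-structure covariates are not fitted by default
(the intended populations show no marked stratification); precomputed
covariates can be supplied.

## Phenotype adjustment

The GWAS response is one value per animal: a linear mixed model with the
fixed factors and a random individual intercept is fitted per trait, and the
exported value is `intercept + mean(record − fitted fixed effects)` over the
animal's records (`residual_mean`). This keeps the observed scale and does
not shrink; the shrunken `blup` export (`intercept + predicted random
intercept`) is available by flag. Whether an analysis should use the
shrinkage-free or shrunken form is genuinely open; downstream results in
this package do not depend on the choice, and the default favors the form
that reduces to the raw mean when factors are null.

## REML

Variance components maximize the REML log-likelihood by average-information
(AI) updates. All algebra runs in individual space: with
`A = σ²_a K + σ²_pe I` the record covariance is `V = Z A Zᵀ + σ²_e I`, and
the Woodbury identity `V⁻¹ = (I − Z B Zᵀ)/σ²_e`,
`B = (σ²_e I + A D)⁻¹ A`, `D = ZᵀZ`, makes every solve n×n in the number of
individuals rather than records. Numerical policy:

- starting values `(0.3, 0.1, 0.6) × var(y)`;
- an AI step is accepted only if the log-likelihood does not decrease,
  halving the step up to 12 times first; otherwise a multiplicative
  EM-style update `θ ← θ · (yᵀPV_iPy) / tr(PV_i)` is taken, so accepted
  iterations never descend;
- the AI system is solved by minimum-norm least squares, which stays finite
  when the AI matrix is singular (e.g. two proportional kinships in a joint
  fit);
- components are pinned at a floor of `1e-10 × var(y)`; with no repeated
  records at all, σ²_pe is fixed at the floor (single-record GBLUP) and
  logged;
- convergence at relative log-likelihood or parameter change `< 1e-8`,
  cap 100 iterations; standard errors are square roots of the inverse AI
  matrix diagonal at the optimum (asymptotic, no profiling).

Kinship matrices are blended with the identity, `(1−β)K + βI` with
β = 0.01 by default, before entering REML or prediction — the standard
conditioning step guaranteeing positive definiteness (a centered G is always
singular). The same blended matrices are used for variance estimation and
prediction.

## Prediction and validation

GEBV solve the mixed-model equations at the estimated variance ratios:
`û = σ²_a K[·, ref] Zᵀ V⁻¹ (y − Xb̂)` with `V` built from the reference
records only, so validation animals are predicted purely through kinship.
On single-record data without blending this is algebraically identical to
centered-marker ridge regression (SNP-BLUP), which the tests verify to
1e-6.

Cross-validation randomizes *individuals* (not records) into five
near-equal folds; every kinship scenario is evaluated on the identical fold
assignment so promotions are paired. Within each fold the variance
components are re-estimated on the reference records by default (no
leakage through the components); fixed global components are available by
flag. The accuracy target is the per-individual mean of adjusted records —
for repeated records there is no single "observed phenotype", and the
adjusted mean is the scalar the pipeline guarantees exists; raw-mean and
first-record comparators are available. The GWAS and top-k% selection are,
by default, computed once on the full data before cross-validation,
mirroring the sequential design of prior-information studies; this leaks
marker ranking into validation folds, and the promotion estimates should be
read as evaluations of that sequential protocol rather than of a fully
nested one.

Scenario differences are lettered from a one-way ANOVA on the fold
accuracies followed by Tukey HSD at α = 0.05; with equal replicate counts
Tukey non-significance is contiguous in mean order, so maximal
non-significant runs become the letter groups.

## Synthetic data

The generator emulates a cashmere-goat breeding study design: a few
thousand animals, ~67k imputed SNPs (scaled down for tests), one to eight
records per animal with the count drawn as `min + Binomial(max−min, ·)`
matched to a target mean (4.26 for most traits), and categorical
herd/year/sex/age effects. Phenotypes are
`mean + breeding value + permanent environment + factor effects + residual`
on a unit-total-variance convention: `σ²_a = h²`, `σ²_pe = rep − h²`,
`σ²_e = 1 − rep`, times an optional scale. Breeding values are QTL-dosage
sums rescaled so their sample variance is exactly σ²_a; QTL effects are
normal or gamma-with-random-sign (the gamma option concentrates the
architecture). Factor level effects are N(0, 0.5²) by default — large
enough that unadjusted analyses visibly suffer, which is the situation the
adjustment stage exists for. Age progresses with record year for a
configurable fraction of animals (default 0.5), reproducing the
longitudinal age–year confounding of real data.

Genotypes are drawn at linkage equilibrium by default — no printed quantity
needs LD — with an AR(1) Gaussian-copula block mode (`ld_rho`,
`ld_block_size`) for exercising the LD-dependent steps. What the simulations
therefore do **not** show: behaviour under genome-wide LD, pedigree
relatedness between reference and validation animals (simulated individuals
are unrelated, so baseline all-SNP accuracies are much lower than in a real
herd), genotyping error, or selection. Passing tests demonstrate the
arithmetic and the statistical calibration of the machinery, not real-data
accuracy levels.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in minutes on one CPU: heritability recovery at n = 1,000
individuals × 5,000 SNPs × 3 records (10 replicates), null calibration at
n = 500 × 2,000 SNPs, and the prior-vs-baseline comparison at n = 800 ×
4,000 SNPs with 80 QTLs (5 replicates). REML oracle checks use n ≤ 30
fixtures against a 31³ dense grid search.

## Known limitations

- The iterative scan is the fixed-effect formulation only; no
  kinship-corrected (MLM) scans.
- Single-trait throughout; no multi-trait REML, no genotype-by-environment.
- SEs of h² and repeatability are not propagated (components only).
- VanRaden method 1 only; no pedigree or single-step matrices.
- The joint two-kinship fit reports a near-unidentified split when
  G₁ ≈ G₂; use separate mode for the weight arithmetic.
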