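# Methods

This note documents the statistical models behind `protmr`, the parameters
that matter, what the synthetic-cohort generator does and does not emulate,
and the design choices made where the design was genuinely open.

## The analysis path

The package targets serum-proteomics case-control cohorts of the elderly
measured on an aptamer panel (thousands of analytes, several analytes may
target the same gene product), genotyped, and staged for a binary disease
such as age-related macular degeneration: no disease, early disease under
two nested grading schemes (a permissive and a strict one), and late
disease split into pure geographic atrophy and neovascular forms, with a
follow-up visit supplying progression labels. A second, independent sample
— in practice a disease GWAS consortium — supplies outcome summary
statistics on the log-odds scale for the Mendelian randomization stage.

## Protein preprocessing

Each analyte is Box-Cox transformed, with the exponent λ chosen by profile
maximum likelihood on the fixed grid [−2, 2] in steps of 0.01 (the
transform family is standard; a grid makes the fit deterministic and
reproducible). Analytes with nonpositive values are shifted by `1 − min`
first; constant analytes have no defined λ and are flagged and passed
through centered at zero. Transformed analytes are centered and scaled to
mean 0, SD 1, so downstream effect sizes are per SD of protein.

Extreme outliers are then excluded by a two-level rule **on the scaled
data**: compute each analyte's 99th percentile, take the 99.5th percentile
of those cutoffs across all analytes as one global threshold, and set
values above it to missing *per value* (a sample losing one analyte keeps
all others; downstream regressions drop missing values case-wise per
model). The order of operations is transform → scale → per-analyte 99th →
global 99.5th → exclusion. The global threshold is computed once and frozen
in the `PrepReport`, which makes the exclusion idempotent: a second pass
removes nothing. All percentiles in the package use the
linear-interpolation quantile convention.

## Association stage

The screen is per-analyte logistic regression of the staged outcome on the
standardized protein with age and sex as covariates; betas are log odds
ratios per SD. The multiple-testing unit is the **unique protein-encoding
gene**, not the analyte: several aptamers can target one protein, so the
study-wide threshold is 0.05 / (number of unique gene symbols) — with 4137
genes, 1.21 × 10⁻⁵ — and reported adjusted P-values are the gene-count
Bonferroni values capped at 1. Outcome contrasts are case-vs-none (early
definitions exclude late cases and vice versa); progression analyses are
the same screen restricted to re-examined baseline-early subjects with
progression to late stage (or pure GA) as the outcome — no separate
machinery.

Quantile profiles cut an analyte into q ∈ {4, 5} rank-based equal-size bins
(ties broken by stable sample order, so bins are deterministic). The
categorical model treats bins as factor levels and reports per-bin
predicted log odds at mean covariate values; the continuous model codes the
bins 1..q numerically. The top-vs-bottom contrast is the marginal
(model-based) difference between the q-th and the reference bin, which in
the dummy coding is exactly the q-th bin coefficient; the reference-bin
contrast is zero by construction.

Module enrichment is the two-sided Fisher exact test on the 2×2 partition
of the analyte universe by (hit, in-module), reporting the sample odds
ratio. The module eigenprotein is the first (optionally second) principal
component of the standardized module submatrix, sign-fixed to correlate
positively with the module mean profile; samples missing more than half the
module's analytes get a missing score (others are mean-imputed for the
decomposition only). The score can be fed back into the logistic screen as
a module-level trait.

## pQTL scan

Per variant × analyte additive-model linear regression (dosage 0–2 of the
effect allele, used as-is without hard-calling), age/sex-adjusted. Records
are labeled *cis* when the variant lies on the gene's chromosome within the
gene body ± 500 kb (closed interval, 1-based coordinates) and *trans*
otherwise; records below the reporting threshold (default 1 × 10⁻⁶) are
flagged reportable. The scan is implemented by Frisch-Waugh
residualization, which is algebraically identical to a full per-variant
OLS fit (tests verify 1 × 10⁻⁸ relative agreement against statsmodels,
keeping the fast path and the reference path separate). Monomorphic
variants are flagged, never silently dropped. Per-analyte exposure summary
statistics (`variant chrom pos ea oa beta se p n`) feed the MR engine.

## Bootstrap-LASSO stability selection

The sampling distribution of penalized logistic coefficients is
approximated by the nonparametric bootstrap: each of B replicates resamples
subjects with replacement (single-class replicates are redrawn, with a
bounded retry), selects the L1 penalty by 10-fold stratified
cross-validated binomial deviance, and refits at the selected penalty with
age and sex left unpenalized via per-feature penalty factors of zero.
Selection records carry the fraction of replicates with a non-zero
coefficient, the mean coefficient, and the 2.5%/97.5% coefficient
quantiles; analytes at or above the threshold fraction (80% of 500
iterations at full scale) are the selected predictors.

Two open choices were fixed as follows. The per-replicate penalty rule
defaults to the **1-SE rule** (the largest penalty whose CV deviance is
within one standard error of the minimum): the CV-minimum rule optimizes
prediction and routinely carries tens of noise features at ~100 candidate
analytes, which defeats support recovery; the minimum rule remains
available (`rule="min"`). The solver is a glmnet-style IRLS + cyclic
coordinate descent with warm-started penalty paths (numba-compiled),
written in-house because no installed Python library exposes per-feature
penalty factors at bootstrap × CV speed; it is cross-checked in the tests
against `statsmodels` L1-penalized logistic regression with a per-parameter
alpha vector.

AUC is the tie-corrected Mann-Whitney statistic with a DeLong confidence
interval. Nested model comparison fits both logistic models by maximum
likelihood and tests the paired AUC difference by a stratified bootstrap
(cases and controls resampled separately, 2000 resamples by default), with
the two-sided P read off the bootstrap distribution's position relative to
zero; identical specifications return a difference of exactly 0 and P = 1.
The bootstrap was chosen because no standard named test exists for nested
in-sample ROC curves.

## Two-sample MR for correlated cis instruments

Exposure effects β_X (SD units, from the exposure sample) and outcome
effects β_Y (log OR, from the independent outcome sample) are combined per
protein over M instruments. Instrument selection: restrict to the cis
window (gene ± 500 kb); set P_b = 0.05/N with N the number of variants in
the window; clump greedily by ascending exposure P (PLINK-style: a retained
index variant removes later variants with r² ≥ 0.2 within 1 Mb); then prune
survivors with P ≥ P_b (clump-then-threshold, following the method's
stated order). An empty survivor set marks the protein untestable — a
result, not an error. LD is the signed empirical dosage correlation in the
exposure sample, which shares its population with the outcome sample.

Harmonization aligns outcome betas to the exposure effect allele (sign
flips on allele swaps, strand flips recognized); palindromic (A/T, C/G)
variants with MAF > 0.42 are dropped as strand-unresolvable. Instruments
missing from the outcome set are replaced by the best in-window proxy with
r² > 0.8 that the outcome set covers; the exposure effect is re-estimated
at the proxy — both samples must refer to the same physical variant — after
which ordinary allele harmonization aligns the outcome effect, and the LD
matrix is rebuilt for the final set.

The GWLS estimator and its SE are given in the README; Σ = ρ ∘ σ_Y σ_Yᵀ is
regularized by adding 10⁻⁶ to the diagonal of ρ when its smallest
eigenvalue falls below 10⁻⁸, and rejected with a condition-number
diagnostic when still effectively singular. α = max(1, √MSE) means a good
fit never shrinks the SE below the fixed-effect value. Exposure-side
standard errors σ_X are carried in the instrument table but unused by the
estimators (the first-order no-measurement-error convention). At M = 1 the
estimator collapses exactly to the Wald ratio (α ≡ 1); at ρ = I it is the
classical IVW estimate.

**Null distribution for the causal P.** The default reference for
θ̂/se(θ̂) is the standard normal. A t reference with M − 1 degrees of
freedom is available (`MRConfig(null_dist="t")`) and reproduces the
reporting convention of analyses with ~25–35 instruments, where t and
normal nearly coincide. The normal default was fixed analytically: with
α = max(1, √MSE) already inflating the SE for overdispersion, a t(M−1)
reference at small M double-counts that correction — at M = 10 the exact
null rejection rate at nominal 5% drops to ≈1.8%, whereas the normal
reference gives ≈3.7% (still slightly conservative because of the α
floor). The recovery studies confirm the normal default is calibrated.

Sensitivity estimators: the **weighted median** of per-instrument ratios,
weighted by their first-order inverse variances, with linear interpolation
of the 50% weighted quantile; its SE is a parametric bootstrap (1000
resamples of β_X and β_Y from their reported normal sampling
distributions, fixed seed). **MR-Egger** is the weighted regression of β_Y
on β_X with an intercept, weights 1/σ_Y², instruments oriented so β_X ≥ 0;
inference is classical WLS with the residual scale estimated on M − 2
degrees of freedom, so the intercept P (t, M − 2 df) is exactly calibrated
under no directional pleiotropy — the α floor is deliberately not applied
here. The **two-step gate**: a protein whose GWLS estimate is significant
after Benjamini–Hochberg adjustment must have a weighted-median estimate
agreeing in sign and significant at P < 0.05 (step 1), and an Egger slope
agreeing in sign with intercept P > 0.05 (step 2), to be a causal
candidate. With M < 3 the sensitivity estimators are undefined and the
protein is recorded as untestable by the gate rather than promoted.

## The synthetic-cohort generator

The generator exists so that every stage has a recovery test with known
truth; it emulates the study *structure*, not any particular dataset.

**Genotypes.** Each LD block draws MAFs uniformly from its range, solves
per pair for the latent-Gaussian correlation that yields the target signed
dosage correlation after thresholding at the MAF quantile, and samples two
independent haplotypes per subject (thresholded latent draws) whose sum is
the dosage — Hardy-Weinberg holds by construction, and the signed LD is
controlled. Infeasible targets (beyond the Fréchet bound for the drawn
MAFs) are rejected with the attainable range. Blocks are mutually
independent and placed on distinct chromosomes by default.

**Proteins.** Each analyte is a sum of per-allele genetic effects (SD
units), a module latent factor with loading √r_module (giving pairwise
within-module correlation r_module), an optional shared confounder loading,
and independent noise sized so the theoretical variance is 1; configured
variance shares above 1 are rejected. Analytes with a cis effect get their
encoding gene placed around that variant; others far away, so cis/trans
labels are known.

**Disease.** logit P(case) = intercept + Σ θ_p·protein_p + Σ direct variant
effects + confounder + age/sex terms (centered covariates). The intercept
is calibrated by the logit-probit approximation so the marginal case
fraction matches the target prevalence despite the random terms. Stage
labels among cases follow multinomial proportions echoing the reference
cohort (early:late ≈ 1755:272; the strict early scheme a 1054/1755 subset;
late split GA-pure : nAMD-only : GA-plus-nAMD ≈ 112:89:71); a re-examined
subset (59%) receives follow-up labels with configurable protein-driven
progression. The direct variant effects violate the exclusion assumption
(the pleiotropy knob); the confounder loadings violate independence (the
IV-2 knob). The baseline prevalence for MR recovery studies is 0.05,
matching an advanced-stage outcome (272/5457): besides realism, a rare
outcome makes the marginal per-variant log-OR nearly collapsible, so the
conditional θ is the recoverable estimand — at common prevalence logistic
non-collapsibility attenuates β_Y by a few percent at θ = 0.5, which is a
property of odds ratios, not of the estimator.

**What it does not emulate:** recombination maps and realistic LD decay,
imputation uncertainty, assay chemistry and batch structure, longitudinal
protein trajectories, or a clinically grounded severity model (stage labels
are proportions, not a liability model). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every failure mode of real data.

## Reference study conditions

The simulation studies behind the tests and `scripts/acceptance.py` use:
two samples of n = 5000; 10 instruments per protein (one block, r = 0.5,
MAF 0.2–0.4, cis effect 0.6 SD/allele) for the recovery grid
θ ∈ {0, 0.25, 0.5} at 200 replicates per condition; 10 independent
instruments with cis effects spread over 0.1–0.45 and a constant direct
variant-outcome effect of 0.3 for the Egger power/null studies (under the
null the estimated-scale t(M−2) intercept test is exactly calibrated,
which is why the no-LD configuration is the right null benchmark); and a
stability-selection benchmark of 3 planted predictors (|log OR| = 0.5/SD,
mixed signs) among 100 independent nulls at n = 1000, case fraction 0.3,
B = 100 — the case fraction keeps events-per-variable adequate, and
independent nulls isolate the selection operating characteristics. In the
recovery studies clumping is disabled (`clump_r2=0.99`) because the GWLS
estimator models the instrument correlation; the default r² = 0.2 would
reduce an r = 0.5 block to a single instrument, which is the intended
production behavior but not the property under study.

## Numerical conventions

Logistic fits use Newton-Raphson with step halving and a relative
parameter-change stopping rule (tests verify 1e-14-level agreement with
statsmodels); separation is reported as non-convergence, never silently.
Quantile bins break ties by stable order; percentiles interpolate linearly;
BH adjustment is the standard step-up (via statsmodels), monotone and
capped at 1. All randomness flows from explicit integer seeds:
simulations through `numpy.random.SeedSequence` spawning, the
weighted-median bootstrap and all resampling loops through seeded
generators, so identical configurations are bit-identical.

## Known limitations

Single-protein (univariable) MR only — no multivariable MR, Steiger
filtering, or colocalization; overlapping cis windows (e.g. paralogous gene
clusters) can make candidate proteins statistically indistinguishable.
The weighted-median SE is bootstrap-based and thus mildly seed-dependent.
The Egger model ignores instrument correlation (the field's standard
practice); its intercept test is calibrated for independent instruments.
Progression modeling is a restriction of the cross-sectional screen, not a
time-to-event analysis.
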