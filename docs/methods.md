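# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of the package.

## Kinship linear mixed model

The association model is `y ~ N(Xβ, σ²_g K + σ²_e I)`, where K is the
block-diagonal genetic-relatedness matrix (1.0 on the diagonal and between
MZ co-twins, 0.5 between DZ co-twins and between siblings, 0 across
families; MZ blocks are singular, which is permitted). Fitting rotates the
data into the eigenbasis of K and profiles the likelihood over
`h = σ²_g/(σ²_g+σ²_e)` with a bounded scalar search (tolerance 1e-10 on h),
so each candidate ratio costs one weighted least-squares solve. Maximum
likelihood is the default, matching the estimation the design calls for;
REML is available as an option. At `h = 0` (or K = I) the fit reduces
exactly to ordinary least squares with the ML residual variance; the two
variance components are then individually unidentified and only their sum
is meaningful.

Single-coefficient tests report `F = (β̂/SE)²` with a Satterthwaite
approximation to the denominator degrees of freedom: the delta method on
the contrast variance with the expected Fisher information of
(σ²_g, σ²_e). When the information matrix is near-singular — identity
kinship, or a variance component at the boundary — the residual df `n - p`
is used instead, and it is also available as an explicit option.
Multi-coefficient Wald tests (study-interaction omnibus, MR stratum
interactions) use the residual df; a Satterthwaite treatment of
multi-degree contrasts adds complexity without changing any qualitative
conclusion at these sample sizes.

Design conventions: Z-scoring uses the pooled sample across all five
studies (n-1 denominator); the quadratic term is the square of the Z-scored
volume, so dropping the Z-transform is a pure reparameterization that
leaves the top-order term's test invariant; ICV is standardized by default
(option `standardize_icv`); missing values are handled by listwise deletion
per fitted model with a logged count; the study factor uses study 5 as the
reference, which is also the reference for interaction contrasts
(omnibus α = 0.05/4, per-contrast α = 0.05). The 14-region scan flags each
term at Bonferroni α = 0.05/14 ≈ 0.0036.

## WLS meta-analysis

Per-study models are the same association model without the study factor.
Fixed-effect pooling uses `w_i = 1/SE_i²`: pooled estimate
`Σw_i b_i / Σw_i`, pooled SE `(Σw_i)^(-1/2)`. The reference distribution
for the pooled p-value of this design is ambiguous in the field's reporting
conventions; the two-tailed normal on `z = estimate/SE` is reported as
primary and a t with k-1 df as a secondary column. No heterogeneity
component (τ²) is estimated: the pooling is deliberately a fixed-effect
(homogeneity) model.

## Two-stage least-squares Mendelian randomization

Stage 1 regresses the exposure on the polygenic-score instrument plus
covariates in the kinship mixed model; stage 2 regresses the outcome on the
fitted exposure plus covariates. To accommodate a nonlinear
exposure-outcome relation, the stage-1 residuals are cut into three
equal-sized strata, contiguous in the residual ordering (remainder goes to
the earlier strata; ties broken by stable input order, so the codes are a
deterministic function of residual ranks). How the stratum variable enters
stage 2 is genuinely open; the default includes both the stratum main
effects and the fitted-exposure × stratum interactions, and `strata=False`
gives the plain estimator, which with no covariates and K = I equals the
textbook instrumental-variables closed form.

Naive second-stage SEs understate uncertainty because the fitted exposure
is less variable than the actual one. The corrected SE rescales by the
residual sum of squares formed with the actual exposure at the second-stage
coefficients (evaluated in the whitened GLS metric) and is the default for
interval estimates. First-stage F < 10 flags a weak instrument without
aborting. The cohort-level wrapper subsets to DNA-available persons
(a generator flag, 636 of 724 by default) and always includes the nuisance
principal-component columns in both stages.

## Multivariate twin model

For p traits per twin, the phenotypic covariance is decomposed as
`Σ_Ph = Σ_A + Σ_D + Σ_E`. Expected pair covariances have diagonal blocks
`Σ_Ph` and cross-twin blocks `Σ_A + Σ_D` (MZ) or `0.5·Σ_A + 0.25·Σ_D` (DZ),
the coefficients being the expected additive and dominance genetic
correlations between twins. Each component is parameterized by its Cholesky
factor, guaranteeing positive semi-definiteness. Means are linear in
covariates (study, age, sex in the pipeline), one coefficient set per
trait, shared across zygosities and co-twins.

Estimation is exact coordinate ascent: a generalized-least-squares mean
update given the covariances alternates with a covariance update given the
means. For the saturated model (free Σ_MZ, Σ_DZ, averaged over twin-order
exchange) the covariance update is the closed-form scatter matrix, so the
alternation is an exact ML algorithm; for biometric models the covariance
update is L-BFGS over the Cholesky parameters (convergence 1e-8 on the
log-likelihood, 5 restarts with fixed jitter seeds). Starting values come
from the moment estimates `Σ_A ≈ 4C_DZ - C_MZ`, `Σ_D ≈ 2C_MZ - 4C_DZ`
projected to the PSD cone. Pairs with a missing co-twin contribute through
the marginal likelihood of their observed entries in `fit_biometric`
(full-information handling, with grouping by missingness pattern); the
saturated baseline uses complete pairs, and the pipeline therefore runs all
compared models on complete pairs so that likelihood-ratio tests share one
data basis. Extra siblings are excluded from twin modeling but retained in
all mixed-model stages.

The omnibus test of the SWB-volume genetic correlations orders SWB first
and fixes the four volume-row entries of the first Cholesky column of Σ_A
to zero, which zeroes exactly the four cross covariances (df = 4); the
environmental analogue constrains Σ_E the same way. Dropping Σ_D from the
5-trait ADE model removes 15 parameters. Tests of variance components on
the boundary of the parameter space have non-standard null distributions;
the naive chi-square p is reported with a caveat flag, as is conventional.
Squared-volume traits are squares of the Z-scored volumes, standardized
before (not after) covariate adjustment.

## LD-score regression

Univariate: weighted regression of z² on ℓ, `h² = slope·M/N`, free
intercept (a constrained-intercept option exists). Bivariate: regression of
z1·z2 on ℓ, `ρ_g = slope·M/√(N1·N2)`, `rg = ρ_g/√(h²_1·h²_2)`. Weights are
the standard heteroskedasticity form `1/(ℓ·(expected statistic)²)` with one
reweighting pass from an initial unweighted fit; an unweighted fallback is
available. Standard errors are delete-a-block jackknife over contiguous SNP
blocks (200 by default, reduced automatically so each block keeps at least
10 SNPs); for rg the entire three-regression pipeline is recomputed per
deleted block. A non-positive heritability point estimate leaves rg
undefined and the result is returned flagged rather than raising — at small
SNP counts the heavy weighting makes this rare but possible.

## Synthetic-data generator

The generator emulates a five-study twin-register MRI design. Under the
default "paper" layout the per-study family composition is fixed —
MZ pairs / DZ pairs / single twins / attached siblings / one MZ+co-sib
triplet family — giving per-study totals (58, 244, 58, 130, 234), 724
persons, and an exact 302/422 M/F split with same-sex MZ pairs. A "random"
layout draws composition from `mz_fraction` and `sib_count_distribution`
instead (triplets off by default there). Twins share age at MRI; sibling
ages differ by 1.5-4 years; age at the well-being assessment is the MRI age
plus a study-specific delay plus noise, keeping the two ages correlated
above 0.9.

Additive-genetic latents are built as `√0.5·(family) + √0.5·(individual)`
with MZ co-twins sharing the individual part, so MZ genetic correlation is
exactly 1 and DZ/sibling correlation exactly 0.5 by construction; dominance
latents use weights (0.5, √0.75) giving the 1/0.25 sharing pattern.
Volumes load on a common factor (cross-region genetic correlation 0.40), a
region factor (left/right genetic correlation 0.95) and a trait-unique
factor; environmental left/right correlation is 0.30. These match the AE
estimates the design reports for hippocampal volumes. A configurable
fraction (0.15) of each volume's variance comes from the ICV latent
(heritability 0.80).

Defaults, chosen once from the study conditions: heritabilities 0.44 (SWB)
and 0.76 (volumes); SWB composite 24.9 ± 4.1 scale units; concave link
lin_beta = 0.74 and quad_beta = -0.33 SWB units per SD of the bilateral
hippocampal composite (the quadratic term is centered so the mean is
unaffected, and the residual scale is shrunk so total SWB variance stays on
target); genetic and environmental SWB-hippocampus correlations 0.07 and
0.18; instrument strength pgs_r2 of 0.015 (SWB) and 0.025 (volumes), the
weak-instrument scale implied by first-stage F statistics near 5-11 at
n ≈ 600; 11 nuisance principal-component columns (3 ancestry + 1 batch + 7
platform in the design being emulated) that are pure noise; a DNA-available
subsample of 636.

SAT (5-35) and HAP (4-28) share no natural metric; the composite rescales
HAP linearly onto the SAT range before averaging, which makes a composite
mean near 24.9 on the SAT scale consistent with the descriptive tables.
The generator draws a latent split so that the composite rule applied to
the emitted SAT/HAP columns reproduces the SWB column exactly. Symptom
selection builds a latent symptom score correlated with SWB (default -0.8)
within each selected study and assigns high/low classes either at fixed
group counts — defaults (23, 35), (75, 167), (23, 35) for studies 1-3 — or
at quantile cuts; class 1 marks unselected persons.

Two interactions of the generative channels are worth knowing. First, the
planted volume→SWB link operates on the *realized* volume, which is itself
heritable, so the synthetic world carries more SWB-volume genetic
covariance than the `rg_swb_vol` parameter alone: the twin-model genetic
omnibus is typically significant here even though the restricted-data study
this design emulates found it null. Second, for the same reason the
mixed-model linear estimate exceeds `lin_beta` (≈1.2 versus 0.74 at the
defaults), since the genetic and environmental correlation channels add to
the planted coefficient. Passing tests therefore demonstrate calibration of
the *methods* under a known generative model, not reproduction of the
restricted data.

What the generator does not emulate: item-level questionnaire responses,
genotypes or SNP-level scores (polygenic scores are emitted directly),
measurement error in volumetry, non-Gaussian trait distributions beyond
the clipping of the SAT/HAP scales, assortative mating, or shared
(C-type) environment.

## Problem sizes and runtimes

The test suite and the acceptance script use: the design-scale cohort
(n = 724) for scans, meta-analysis, MR and twin stages; 5,000 pairs per
zygosity for heritability-recovery checks; 500 replicates for the
mixed-model type-I-error and the 2SLS coverage simulations (n = 400 per
replicate); 100 replicates at M = 2,000 SNPs for the LDSC recovery check.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances; everything runs in about a minute on one core.

## Known limitations

- No ACE (shared-environment) twin variant, sex-limitation or
  age-moderation models.
- SNP-level MR estimators (IVW, Egger) are out of scope; the design is
  single-score 2SLS.
- No annotation-stratified LDSC, and LD scores are inputs or simulated,
  never computed from genotype panels.
- Multi-coefficient mixed-model tests use residual df rather than a
  Satterthwaite generalization.
- The saturated twin baseline requires complete pairs.
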