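# Methods

This note documents the models, defaults and numerical choices behind pdrisk,
and what the synthetic-data tests do and do not establish about real data.

## The synthetic cohort

All analyses run on cohorts generated by `pdrisk.simulate`. The generator is
not a population-genetics simulator; it is the minimal structure that makes
every downstream stage estimable against a known truth.

**Genotypes.** Haplotypes are drawn per LD block from a latent AR(1) Gaussian
process with lag-1 correlation `ld_decay` (default 0.8, blocks of 10
variants), thresholded at Φ⁻¹(maf) so each allele has its target frequency;
dosage is the sum of two haplotypes. Within-block dosage correlation decays
geometrically with distance; blocks are independent. Blocks are laid out in
genome order over 22 autosomes with 10 kb spacing inside a block and 600 kb
between blocks, so a 250 kb clumping window spans a block but never bridges
two. MAFs are uniform on `maf_range` (default 0.05–0.5). Missingness is
completely at random (default 2%). About 4% of variants are made palindromic
(A/T or C/G), ~2% are given low imputation-quality metadata and ~1% extreme
Hardy–Weinberg p-values, purely to exercise the QC filters; causal variants
are drawn from the remaining clean variants with effect magnitudes uniform on
0.08–0.25 (random sign), which at the default simulated GWAS size
(N = 100 000) makes every causal variant genome-wide significant — the regime
in which threshold-selection recovery is a well-posed check.

**Summary statistics.** β̂ = β_true + N(0, se²) with
se = 1/√(2·N·maf·(1−maf)) and two-sided Wald p-values — the large-sample
behaviour of a logistic GWAS, not a re-run GWAS.

**Phenotypes.** Disease follows
`logit P = β₀ + β_age(age−60) + β_sex·male + β_prs·g + Σβ_e x_e + Σγ_e x_e·g`
with `g` the standardised latent genetic score. Defaults: β₀ = −3.4 at age 60,
β_age = 0.07/year, β_sex = 0.45 (male excess), β_prs = ln 1.5 per SD, exposure
prevalences and log-odds effects mirroring well-replicated incident-PD
estimates (family history OR 2.19, depression 1.76, epilepsy 2.87, low alcohol
1.39, daytime sleepiness 1.33, current/previous smoking 0.65/0.88, diabetes
1.27, gastric ulcer 1.69, constipation 1.28, anxiety 1.30, coffee null).
Current and previous smoking are drawn from one multinomial so they are
mutually exclusive. The baseline gives a case prevalence of roughly 4–6% —
far above the ~0.4% of a real population cohort — deliberately, so that
logistic models are estimable at desk-scale n; every recovery test should be
read as "the estimator recovers the generative parameter", not as a
statement about power at population prevalence. Cases are flagged incident
with probability `incident_fraction` (default 0.6); age at diagnosis is
`65 − 0.5·g + N(0,5)` years, giving the negative PRS–onset association the
pipeline is expected to recover. PCs are low-variance Gaussians with an
ethnicity-linked offset; ethnicity is a label (94% `white_british`).

The disease model is logistic rather than liability-threshold so that the
analysis model is correctly specified and recovery is exact in expectation.
One integer seed drives split sub-streams per component (genotypes, summary
stats, phenotypes, kinship); identical config + seed ⇒ byte-identical output.

**What this does not emulate:** realistic human LD maps, admixture,
imputation, X chromosome, genotyping batch effects, exposure measurement
error, time-varying exposures, or competing mortality. Passing tests show the
estimators and plumbing are correct, not that real-data effect sizes will be
reproduced.

## QC

Variant filters run in a fixed order (each on the survivors of the previous):
presence in both genotypes and summary statistics, duplicate rsIDs (first
kept), duplicate positions (first kept), palindromic pairs, missing rsIDs,
then MAF < 0.01 (strict), missingness > 0.10 (strict), HWE p < 1e-6, info
< 0.3. MAF and HWE use supplied metadata when present; otherwise MAF is
computed from dosages and HWE by an exact conditional test (implemented
in-package; no installed library exposes one). Sample filters: missingness
> 0.10, then the ancestry label. Relatedness pruning builds the graph of
pairs at kinship ≥ 0.0442 and greedily removes the highest-degree node (ties
to the lexicographically smallest id) until no edge remains — deterministic,
and retains more individuals than naive "drop one per pair" in clusters.

## Clumping-and-thresholding PRS

Candidates form a 10×5 grid (p thresholds 5e-5…1; r² thresholds 0.1…0.8;
250 kb window). Clumping is greedy: visit variants by ascending p (ties by
position then rsid); each unclaimed variant indexes a clump and claims
unclaimed same-chromosome variants within the window whose squared Pearson
dosage correlation on the reference panel (pairwise-complete) reaches the
threshold. The p filter is strict (`p < t`) except t = 1, which keeps
everything. The reference panel is a ~503-individual subsample (the size of a
typical external European reference panel); r² on 503 haplotype pairs is
noisy in the third decimal, which matches practice.

Per-locus score = effect-allele dosage × β. The ambiguity of "standardise
each SNP" is resolved as standardising the per-locus *score* (dosage×β), with
mean/SD estimated on training individuals only and frozen into the model —
the choice is recorded in the model's JSON sidecar. A missing or absent locus
contributes the per-locus mean, i.e. exactly 0 after standardisation; a
genotype file counting the other allele is flipped (2 − dosage); >50% absent
loci is an error. Selection maximises Nagelkerke pseudo-R² of
`status ~ age + sex + deprivation + PC1–4 + PRS` over the covariates-only
null on the training split; ties go to fewer SNPs; non-converged candidates
are excluded. All cases (prevalent + incident) are used for PRS training and
selection; incident-only case–control sets are used for association,
PREDICT-PD evaluation and interaction.

The "known-loci-excluded" score removes variants within 1 Mb (inclusive) of
lead SNPs and refits standardisation. In the pipeline, leads are derived from
the simulated GWAS itself (genome-wide significant variants clumped at
r² = 0.1), the closest self-contained analogue of published risk loci.

## PREDICT-PD

Baseline odds `1/(1 + 28.53049 + 73.67057·e^(−0.165308(age−60)))` — positive,
strictly increasing in age, asymptote 1/29.53049. Trait multipliers are
applied independently (female sex divides by 1.5); multiplication is
commutative so application order is irrelevant (tested over all flag
subsets). Missing traits count as absent; erectile dysfunction is skipped,
not imputed, for women; "anxiety or depression" is the logical OR of the
cohort's separate anxiety and depression fields.

## Association and FDR

Per-exposure models: `status ~ age + sex + ethnicity + deprivation +
exposure`, complete-case, maximum likelihood (statsmodels Newton; tolerance
1e-8). Cohort: incident cases plus all non-PD controls; prevalent cases
excluded. Sex-specific exposures drop the sex covariate. Degenerate
exposures, separation and non-convergence yield flagged results, never
silent estimates. LRT compares against the covariates-only null; FDR is
Benjamini–Hochberg step-up over the exposure family at 0.05 ("local FDR"
variants were considered and rejected as the less conventional reading). The
combined model jointly fits all FDR-passing exposures; rank-deficient designs
are flagged wholesale. The matched sensitivity design samples exactly 4
controls per case with identical sex/ethnicity and age within ±1 year (exact
age matching empties strata at desk scale), without replacement,
deterministically under a seed; cases with fewer eligible controls are
dropped with a warning.

## Interaction

RERI and AP are evaluated exactly from the fitted coefficients. Continuous
factors (the PRS, age at menarche) are inverse-normal transformed with the
Blom offset, Φ⁻¹((r−3/8)/(n+1/4)), average ranks for ties; the AP contrast
is then per 1 SD of the transformed factor and is labelled as such in the
output. AP confidence intervals use percentile bootstrap over individuals
(2.5th/97.5th percentiles; default 5000 replicates, 500 in the desk-scale
runs), resampling the whole dataset without case/control stratification.
Bootstrap refits use an in-package Newton solver warm-started at the
full-data estimate (validated against statsmodels to 1e-6); replicate
failures are counted and >10% flags the result. The multiplicative test is
the 1-df LRT of the interaction term, BH-adjusted across the exposure family.
Family-history exposures are excluded from the interaction family (they
overlap the PRS), and smoking is collapsed to ever/never.

## Evaluation

The 30/70 split is stratified by case status (stabilises metrics at small n)
and seeded; training individuals never touch test-set metrics (perturbing
test rows leaves the fitted PRSModel bit-identical — tested). Nagelkerke
R² = Cox–Snell / (1 − exp(2·ll_null/n)). AUC is the tie-corrected rank
statistic. Calibration is reported as slope/intercept of outcomes regressed
on predicted log-odds (slope 1, intercept 0 = perfect); Hosmer–Lemeshow is
omitted as deprecated. Model comparison fits (a) PREDICT-PD log-odds + PC1–4,
(b) a + PRS, (c) a + known-loci-excluded PRS, reporting each model's metrics
and the incremental R² and LRT of (b) and (c) over (a). Bootstrap CIs for
metrics use the normal approximation (estimate ± 1.96·SD over replicates).

## Problem sizes and runtime

The packaged configuration runs 5000 individuals × 500 SNPs through all
stages in well under a minute on one core. The heavier property checks use
the sizes at which their statements hold: additive-null AP coverage over 20
cohorts of n = 5000 with 500 bootstrap draws; interaction recovery of
β = −0.40 at n = 200 000 over 10 seeds; decile monotonicity at n = 100 000;
threshold-selection recovery at n = 20 000 over 10 seeds. Dosages are stored
float32 (NaN = missing) so the largest simulations stay within a few hundred
MB.

## Known limitations

* The generator's prevalence and effect sizes are desk-scale study
  conditions, not population calibration; absolute R²/AUC values are not
  comparable to population-cohort reports.
* LD is block-diagonal AR(1); clumping behaviour near real recombination
  hotspots is untested.
* The ancestry restriction is a label filter; no PCA-based assignment.
* Interaction APs for continuous×binary pairs depend on the per-SD contrast
  convention; other contrasts (e.g. extreme deciles) would give different
  magnitudes.
* The exact-test HWE fallback assumes autosomal biallelic genotypes.
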