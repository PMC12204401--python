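# Methods

This note records the statistical procedures `mrhaz` implements, the
assumptions they make, the defaults and why they were chosen, and what
the synthetic cohorts do and do not establish about real data.

## Outcome model and estimation

The additive (Aalen) hazard model is
`h(t|X) = h0(t) + γ(t)ᵀZ + θ(t)ᵀE + β(t)ᵀG`. Estimation targets the
cumulative coefficients `B_j(t) = ∫₀ᵗ β_j(s) ds` by least-squares
increments: at each distinct event time the increment is
`(XᵀX)⁻¹ Xᵀ dN` over the at-risk set, with tied events processed jointly
in one increment (the standard Aalen convention; stable on coarse time
grids). The pointwise variance is the optional-variation estimator
`(XᵀX)⁻¹ Xᵀ diag(dN) X (XᵀX)⁻¹` accumulated over event times. Curves are
frozen at the first event time where the at-risk design loses rank; an
intercept-only fit therefore reproduces the Nelson-Aalen estimator
exactly, and a single-binary-covariate fit without censoring reproduces
both groups' Nelson-Aalen curves (algebraic identities used as test
oracles, together with a fixture cross-checked against R's
`survival::aareg`).

**Test time.** The per-covariate test is `B_j(t*)/SE(B_j(t*))`, a
two-sided normal test. The natural-looking choice t* = last estimable
event time is badly behaved: the final increments are computed on at-risk
sets barely larger than the column count p, their variance dominates the
optional-variation SE, and in simulation the statistic loses roughly half
its power relative to earlier evaluation points. `mrhaz` therefore
evaluates the test at the last event time with at least p + 20 subjects
at risk, falling back to the last estimable time when no event time
qualifies (so small closed-form fixtures are unaffected). The literal
endpoint statistic remains available via `test_time="endpoint"`, and a
supremum-type statistic over the whole curve (Brownian-motion reference
distribution) via `sup_test=True` for sensitivity analysis. Null
calibration of the stable-time test is verified by simulation (rejection
rate ≈ 0.05 at α = .05; see the acceptance suite).

**Cox model and LRT.** The pleiotropy screen and the prognostic
likelihood-ratio test use Cox proportional hazards, fitted by
Newton-Raphson on the Efron-tie partial likelihood with step-halving,
convergence at coefficient change < 1e-8, and explicit failure on
constant columns or monotone likelihood (separation), naming the
covariate. Coefficients, SEs and log-likelihoods agree with lifelines to
numerical precision (cross-checked in the tests). The nested LRT is
computed on Cox models because additive-hazard fits have no conventional
likelihood; this is an interpretation the package makes explicit rather
than hides.

## MR funnel conventions

- **cis window:** ±1 Mb of the TSS, inclusive at both ends, same
  chromosome.
- **eQTL scan:** per (gene, SNP) OLS with covariates (gender, age, BRAF,
  all-RAS, batch indicator columns with the first batch as reference, and
  the enriched cell abundances; a compositionally closed abundance set
  has its last column dropped to avoid intercept collinearity).
  Implemented by Frisch-Waugh residualization; identical to the full
  regression (checked against statsmodels).
- **Gene-level p:** Freedman-Lane-style residual permutation — covariate
  residuals of expression are permuted, the best |correlation| against
  the residualized cis dosages is compared with the observed best, and
  `adjusted_p = (1 + #exceedances)/(1 + n_perm)`, honoring the
  1/(n_perm+1) floor. Raw-phenotype permutation would inflate the null
  when covariates structure expression. Adaptive mode stops after 100
  exceedances. Default n_perm = 1,000 at desk scale; 10,000 available.
- **Instruments:** candidates at nominal p < .05; average-linkage
  hierarchical clustering on distance 1 − r² cut at r² = 0.1; the
  smallest-p SNP represents each cluster (ties broken by genomic
  position). Average linkage does not by itself guarantee the
  representatives are mutually uncorrelated, so they are greedily thinned
  (best p first) until all pairwise r² ≤ 0.1 — the invariant the
  selection must deliver.
- **Pleiotropy guard:** per-instrument Cox fit of OS on dosage plus
  gender, age, all-RAS and the first expression PC (computed on autosomal
  genes only — chromosome-Y rows would re-encode sex and collide with the
  gender covariate). Exclusion at Wald p < 1e-4. Tumor location and KRAS
  columns are included when present and skipped in simulation.
- **Prediction:** one-sample weights are the *marginal* per-SNP eQTL
  betas (`ĝ = Q W`); two-sample weights are the *joint* least squares
  `(QᵀQ)⁻¹Qᵀg` — the asymmetry is intentional fidelity to the two
  formulas, not an accident. Dosages are centered (at discovery means for
  the validation cohort) so the hazard intercept absorbs no prediction
  offset. A singular Gram matrix falls back to ridge with penalty
  1e-8·trace, logged. The correlation gate is Pearson on the log2 scale,
  strictly > 0.5.
- **Thresholds:** screen p < .1; causal test p < .05 (the operative
  significance level for declaring causality, with the screen
  deliberately looser); eGene adjusted p < .05; all strict inequalities.
  Predicted genes entering an arm's causal model are that arm's screen
  survivors.

## Preprocessing conventions

Gene filter: keep SD ≥ 0.5 (ddof = 1) and zero fraction ≤ 30%.
Upper-quartile normalization divides each sample by the 75th percentile
of its nonzero values and rescales by the global mean of those quartiles
(the rescaling constant is a declared choice; any constant yields the
same downstream statistics), then log2(x+1) — the unit pseudocount is
likewise a declared default. Samples with > 50% zero genes are removed in
the same operation. Genotype QC drops SNPs at call rate < 99%, exact-test
HWE p < 1e-8 (Wigginton-style enumeration of the heterozygote count —
small-sample safe where the chi-square test is not), MAF < 5%; then
samples at call rate < 90% on the retained SNPs; one pass each, no
iteration; remaining missing dosages are mean-imputed per SNP because the
MR algebra needs complete matrices (upstream imputation pipelines are out
of scope). Cell types are "enriched" at ≤ 30% zeros and SD strictly
> 0.12. Genetic sex is 2-means on chrY expression with the
higher-expression cluster labelled male.

Enrichment medians are study-wide (as the beneficial/non-beneficial rule
states); Kaplan-Meier dichotomization uses the within-arm median by
default with a `split="study"` flag, since the convention there is
genuinely ambiguous. Median ties go to the low/below side, making the
splits deterministic. Paired tumor/normal differential expression is a
paired t-test on log2 differences (Wilcoxon signed-rank behind a flag);
fold change is 2^(mean log2 difference).

## Synthetic cohorts

The generator reproduces the causal structure the analysis assumes:

- **Genotypes.** Gaussian-copula blocks: two latent AR(1) haplotype
  vectors per sample thresholded at allele-frequency quantiles. This
  controls LD and MAF jointly and keeps HWE. Thresholding attenuates the
  latent correlation (the copula-implied dosage correlation is the test
  oracle). Default MAF range 0.10–0.50 — common variants, comfortably
  above the 0.05 QC floor at desk-scale n; the generator refuses runs
  whose realized MAF drops below 0.04.
- **Expression.** Per-eGene cis effects scaled so the cis heritability is
  `eqtl_h2` (default 0.3); a standard-normal cell-composition confounder
  u loads on all genes (strength 0.3) and tilts the first simulated cell
  type's abundance; total non-mean variance 1. A Poisson raw-count matrix
  with log-normal library factors is emitted for exercising
  normalization. Three chrY marker genes keyed to true sex support the
  sex check.
- **Survival.** Constant-in-time additive hazard per subject: baseline
  plus small covariate effects (age N(60,10), gender Bernoulli(0.5),
  BRAF 10%, all-RAS 15% — chosen for realism, not fitted), the
  confounder, the planted arm-specific gene slopes, and any planted
  direct SNP effects; event times are exponential given the hazard.
  Negative hazards are floored at zero and the generator refuses > 5%
  flooring. Censoring is independent uniform with the horizon solved by
  bisection so the expected censored fraction equals the target (default
  0.30, within ±0.05 empirically at n ≥ 1000). The validation cohort's
  survival is driven by the latent *genetic* component of expression —
  the part transported instruments can predict — while discovery survival
  uses full observed expression. The generator's time unit is arbitrary;
  "months" is a reading convention.
- **CMS labels.** Multinomial logit tilted by two designated genes
  (default: the first two eGenes), with configurable strength so
  enrichment tests can plant > 70% rates.
- **Paired tumor/normal.** Per-pair random intercepts; `paired_noise_sd`
  is the SD of the per-pair log2 difference (each measurement gets
  sd/√2), the scale the paired test operates on.

**Named scenarios.** `null_scenario` (300/arm, 40 eGenes, no gene→OS
effects) probes type-I error. `planted_causal_scenario` (800/arm
discovery, 600 validation, 40 eGenes, three arm-specific causal genes at
slope 0.08/month with baseline hazard 0.2/month) probes recovery; the
slope/baseline pair was calibrated by Monte Carlo for ~80–90% marginal
power of the causal test, the maximum the negative-hazard constraint
permits, and the cohort size follows from the fixed effect size. Each
causal gene's heritability is spread over five weak, nearly independent
cis SNPs (ld_rho 0.25): with few strong causal SNPs, each instrument's
own expression-mediated OS association crosses the 1e-4 pleiotropy
threshold and the guard destroys *valid* instrument sets — an
architecture, not a threshold, decision. `pleiotropy_scenario` (n = 2000)
plants one SNP with a direct hazard effect (0.0065/month per allele,
calibrated for ~90% exclusion power at p < 1e-4).

**What passing does and does not show.** The synthetic cohorts have
disjoint cis blocks, no trans effects, no population structure, a single
global confounder, constant-in-time hazards and exponential event times.
Recovery and calibration under these conditions validate the *machinery*
— formulas, thresholds, stage plumbing, test calibration — not the
biological conclusions reachable on any real cohort, where LD is
genome-wide, confounding is richer, and effects drift in time.

## Problem sizes

The test suite runs the null calibration at 400 replicate cohorts of
600 samples, the recovery/replication checks at 100 replicates of the
planted scenario, and the pleiotropy guard at 50 replicates of 2000
samples; the acceptance script uses 100/40/25 replicates of the same
scenarios. These sizes put Monte-Carlo error comfortably inside the
asserted margins while keeping a full run in minutes on one CPU.

## Known limitations

- Only time-varying *coefficients* are supported, not time-dependent
  covariate values; no frailty or interval censoring.
- The permutation scan permutes covariate residuals directly (the common
  Freedman-Lane shortcut); exactness is Monte-Carlo, verified by the
  uniformity acceptance check.
- The supremum test's Brownian reference ignores estimation noise in the
  variance time change; it is a sensitivity tool, not the primary test.
- trans-eQTLs, conditional multi-signal eQTL mapping, summary-statistic
  MR estimators (IVW/Egger/weighted median) and penalized TWAS weight
  training are out of scope.
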