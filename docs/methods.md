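# Methods

`protclock` implements a proteomic aging analysis: an elastic-net clock that
predicts chronological age from a plasma protein panel, the derived
*proteomic age acceleration* (predicted minus chronological age), genetic
association analysis of that acceleration with a procedure that separates
single-pQTL-driven signals from broadly acting ones, phenotype/survival
models of proteomic age, and two-sample Mendelian randomisation. Because
individual-level biobank proteomics cannot be redistributed, the package
ships a synthetic-cohort generator whose planted ground truth makes every
stage testable end to end.

## The synthetic cohort generator

Per sample *i*, protein *p*, variant *v*:

- age_i ~ Uniform(40, 70) years; sex_i ~ Bernoulli(1/2);
- a latent biological-age offset b_i ~ N(0, τ²), τ = 3 years by default;
- genotype dosages g_iv ~ Binomial(2, maf_v) under Hardy–Weinberg, variants
  independent by default; an optional block-LD mode applies an AR(1)
  correlation to latent Gaussian haplotypes before thresholding at the
  allele-frequency quantile, giving realistic pairwise dosage R² within
  blocks (used by conditional-analysis tests);
- protein abundance (log2 NPX-like units)
  x_ip = μ_p + a_p·(age_i + b_i) + s_p·1[male] + Σ_v γ_vp·g_iv + ε_ip,
  ε ~ N(0, σ²), σ = 0.5 NPX.

Half the panel is age-responsive with slopes a_p ~ N(0, 0.02² NPX/yr) —
i.e. a single protein is a weak age predictor (per-protein R² ≈ 0.05–0.1)
but a few hundred proteins jointly support a clock with 2–3 year error,
which is the regime published plasma clocks occupy. The latent offset
enters the proteins as an *age offset* (age + b), so a clock trained on age
transfers its weights to b and the acceleration estimates b; this is the
minimal structure under which "proteomic age acceleration" is a meaningful
target. b also drives mortality (hazard h₀·exp(θ·b), h₀ = 0.02/yr,
θ = 0.1/yr, right-censored at 14 years) and disease
(logit = −6 + 0.05·age + 0.08·b), so the survival and outcome analyses have
a real signal to find.

Missingness is missing-completely-at-random at a 2% base rate; designated
samples/proteins are pushed above the 10% QC threshold (with a
deterministic top-up, since a Bernoulli draw only exceeds the threshold in
expectation) so the filters always have something to remove. MCAR is a
simplification: real assay missingness is partly abundance-dependent, so
passing QC tests here says nothing about informative-missingness bias.
Proteins are conditionally independent given age, sex, b and genotype; real
panels have correlated residuals (shared pathways, batch), which mainly
means the synthetic clock's CV error is better-behaved than a real one's.
Survival event times are drawn before censoring is applied, so shortening
follow-up recensors the same event times (used by a monotonicity test).
Named, independently seeded random streams (samples, protein parameters,
genotypes, noise, survival, outcomes, missingness) make the protein panel's
parameters independent of the sample count and keep stage randomness
decoupled.

### The planted classification scenario

`classification_scenario` fixes the study design used to validate signal
classification (n = 3000, 300 proteins, MAF 0.3 for both planted variants):

- **cis-pQTL**: one target protein — the panel's most age-responsive, with
  its slope pinned at 0.12 NPX/yr (a GDF15-like marker, heavily weighted by
  the clock) — shifted 1.2 NPX per allele. The variant reaches genome-wide
  significance on acceleration *only* through this protein.
- **widespread factor**: 0.04 NPX per allele on the 60 next most
  age-responsive proteins, sign-aligned with each protein's aging
  direction. Aggregate |z| on acceleration ≈ 8; per-protein pQTL |z| ≈ 2,
  so most targets sit below the Bonferroni detection threshold.

These effects came from an upfront power analysis, not iteration against
test outcomes. Two regimes are worth recording. First, a cis effect on
acceleration is self-limiting: the larger γ, the more the target protein's
variance is variant-driven and the more the elastic net down-weights it, so
the product (weight × γ) is maximised near γ ≈ 1 NPX/allele — a cis signal
can only be genome-wide detectable at n = 3000 if its target is also
strongly age-weighted. Second, a widespread variant with a few *detectable*
targets would have all of them excluded, wrongly attenuating the signal;
widespread action is only distinguishable when the per-target effects are
individually sub-threshold but numerous.

## Pre-processing

Samples with >10% missing proteins are removed first, then proteins with
>10% missingness *across the remaining samples* (strict inequalities; a
row/column at exactly 10% is kept). The order matters on edge cases and is
part of the contract. Remaining gaps are filled with sex-specific observed
means; observed values are never altered, and a protein with no observed
value in a needed sex stratum is an error rather than a silent fill.

## The clock

Elastic net on standardised features, objective

    (1/2n)·Σ(y − β₀ − xβ)² + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²),

α = 0.5, intercept unpenalised, no feature pre-selection. λ is chosen by
10-fold cross-validation minimising mean validation RMSE over 61 log-spaced
points on [10⁻⁴, 1] (the grid contains 10⁻³ exactly, the scale at which
large-cohort plasma clocks typically land); ties go to the stronger
penalty. Folds are a seeded uniform partition; each fold standardises on
its own training block. The final model is refit on all data at the chosen
λ and reported on the original feature scale. Coordinate descent is
scikit-learn's; the exact λ = 0 limit is solved by least squares directly.
In-sample and out-of-fold (fixed folds, fixed λ) metrics are both reported,
labelled, since in-sample R/MAE flatter the fit. A sex-stratified mode
trains disjoint per-sex clocks whose predictions tile the cohort.

Acceleration is predicted minus chronological age, exactly, with no
further residualisation; analyses that need age adjustment (the KM decile
grouping) do their own.

## Feature importance

Two stages: screen to the top 100 proteins by |coefficient|, then rank by
mean |Shapley value| and keep the top 20. The Shapley estimator is
permutation sampling: per draw a random feature ordering is walked,
features flip from "hidden" (background = training means, an
independent-feature interventional reference) to "revealed", and the
prediction increments are averaged. One permutation per draw is shared
across samples, which keeps the estimator unbiased and allows a single
batched evaluation per draw. For the linear clock the exact value is
β_f·(x_f − mean_f); the estimator never uses linearity, but tests compare
against that closed form, and the draw count is exposed since convergence
is problem-dependent.

## Association analyses

Per-variant tests are exact OLS Wald tests of acceleration on dosage plus
covariates (default: sex), computed for all variants at once by
Frisch–Waugh–Lovell residualisation; the equivalence with per-variant full
regressions is unit-tested. There is no mixed-model relatedness correction
— synthetic cohorts are unrelated — and the covariate matrix is the hook
for principal components on real data. Two-sided p-values use the t
distribution with residual degrees of freedom, floored at 10⁻³⁰⁰. Variants
must have MAF strictly above 0.1% (configurable).

Signals are selected greedily: repeatedly take the smallest-p variant below
5×10⁻⁸ not inside an already-claimed 1 Mb window (ties: position, then ID).
Secondary signals are confirmed by exact joint regression with the lead and
kept only if conditionally significant and nearly unlinked (dosage
R² < 5%); near-copies of the lead (R² ≥ 0.99) are skipped. Positions are
1-based; windows are closed intervals.

pQTL scans regress each protein on a lead's dosage with a Bonferroni
threshold 0.05/(number of protein tests) — computed from the supplied
count, never hard-coded; a 1463-protein panel gives 3.4×10⁻⁵. Gene burden
tests collapse qualifying-variant carriers to a 0/1 dummy dosage (a carrier
of three variants still counts one) and run the same covariate-adjusted
OLS.

## Signal classification

For each signal: find its pQTL protein set, retrain the clock from scratch
with those proteins excluded — same λ grid and fold seed, fresh CV, so
pre/post differences are attributable to the exclusions rather than
resampling (both λ values are recorded) — recompute acceleration, and
re-test the signal with identical covariates. Verdicts: `single_pqtl_only`
(one excluded protein and the post-exclusion p at or above threshold),
`pqtl_driven` (post p at or above threshold), `widespread` (association
survives). The "still associated" threshold defaults to the genome-wide
5×10⁻⁸ and is stated in the output; an empty pQTL set means nothing can be
excluded and is reported as widespread with a flag. The attenuation ratio
post_beta/pre_beta is reported so other decision rules can be applied
downstream.

## Outcomes and survival

Outcome regressions use the design [1, proteomic age, chronological age,
chronological age², (sex)] — logistic for binary outcomes (odds ratios),
OLS for continuous ones — reporting Wald 95% CIs for both age terms; the
squared term stops the proteomic term absorbing simple curvature in age.
Perfect separation is flagged and the estimate withheld. Proteomic age
(not acceleration) is the default exposure; acceleration can be passed
instead.

The mortality model is Cox proportional hazards on proteomic age adjusted
for age at recruitment and sex (lifelines; Efron tie handling — ties are
measure-zero for the continuous synthetic times). HR = exp(β),
CI = exp(β ± 1.96·se). Proportionality is checked with scaled Schoenfeld
residuals against identity-transformed time, per covariate, plus a global
chi-square that sums the per-covariate statistics (an omnibus
approximation). Kaplan–Meier curves with Greenwood intervals compare the
oldest decile of *age-adjusted* proteomic age (OLS residual of predicted on
chronological age, top 10%) against the rest, with a log-rank test. A
small Breslow score test at β = 0 is included as an independent cross-check
of the Cox machinery against the log-rank statistic.

## Mendelian randomisation

Instruments arrive pre-selected as effect pairs. Harmonisation aligns
outcome alleles to exposure alleles (flipping the outcome beta for swapped
or strand-complement labels), drops palindromic A/T–C/G instruments
(strand unresolvable without frequencies), and orients every instrument to
positive exposure effect — the orientation Egger needs. IVW is the
no-intercept weighted regression (weights 1/se_out²), fixed-effect SE by
default with a multiplicative random-effects option; its algebraic identity
with the weighted Wald-ratio mean is asserted on every call. MR-Egger adds
the pleiotropy intercept and inflates both SEs by max(1, √(Q/(k−2)))
(multiplicative random effects), with t-based p-values on k−2 df. The
generator's MR module draws half-normal exposure effects and Gaussian
outcome noise with the reported SEs, so estimator calibration is exact by
construction; with `se_scale = 0` outcome SEs are reported as 1 to keep
weights defined in the noiseless limit.

## Numerical and design choices

- Thresholds (5×10⁻⁸, 10% missingness, Bonferroni 0.05/n, R² < 5%,
  MAF > 0.1%) live in the pipeline config with these defaults.
- A single global seed fans out to per-stage seeds through a fixed named
  sequence, so toggling one stage does not shift another's randomness;
  manifests contain no timestamps and reruns are byte-identical.
- Constant protein columns get unit scale during standardisation (their
  coefficients stay zero) rather than dividing by zero.
- VCF dosage is the ALT (= effect) allele count; missing genotypes are
  mean-imputed per variant with a logged count, and variants over 10%
  missing are dropped, mirroring the protein-side policy. Multiallelic
  records are skipped with a warning.
- Monte-Carlo replication sizes in the validation suite: 50 replicates for
  signal classification (n = 3000 × 300 each), 200 for Cox and MR recovery,
  10,000 variants for scan calibration — sizes chosen to keep the whole
  suite in single-digit minutes on one core while leaving the Monte-Carlo
  error of each rate well under the margins being asserted (the 2-SE
  coverage checks are the exception: their 95% bar sits within binomial
  noise of the estimator's nominal 95.45%, so those rates hover at the
  bar by construction).

## Known limitations

- No linkage-disequilibrium maps, population structure, relatedness, batch
  or plate effects; passing tests here does not validate behaviour under
  those phenomena.
- The clock is linear; non-linear protein–age relationships are folded
  into noise.
- The Schoenfeld global test is a sum of marginals, not the full
  covariance-aware omnibus statistic.
- Burden testing takes qualifying-variant carrier sets as input; variant
  annotation and QC are out of scope.
- MR instrument selection (clumping, F-statistics, Steiger filtering) is
  out of scope; instruments are assumed valid and pre-pruned.
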