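# Methods

## Score model

The package implements the additive weighted polygenic risk score: for
sample *i* over a panel of M biallelic variants with risk-allele dosages
g_ij ∈ {0,1,2} and weights β_j = ln(OR_j),

    sum mode:      PRS_i = Σ_j β_j g_ij
    average mode:  PRS_i = Σ_j β_j g_ij / (2 · M_i)

with M_i the number of variants observed (non-missing) for sample *i*.
Average mode is the default: it matches the per-allele-average
convention of the widely used PLINK scorer and keeps scores on a
comparable scale when samples differ in missingness. Missing data are
handled mode-specifically: sum mode mean-imputes a missing cell as
2·p̂_j (p̂_j = in-sample frequency of the counted allele) before
summing; average mode sums observed cells only and shrinks the
denominator, i.e. the no-imputation behaviour of the same scorer. The
two conventions coincide up to the constant 2M with complete data and
then induce identical sample rankings, so downstream AUROCs agree.
Which convention an upstream study used is often unrecoverable from its
text; both are first-class here and the mode is recorded in the score
output.

Weights are re-oriented before scoring so every β_j ≥ 0 (a negative
weight flips effect/other allele and negates), making the effect allele
the risk allele everywhere; this leaves score differences and rankings
unchanged and makes the summed risk-allele count Σ_j g_ij well defined.

## Harmonization

Genotype files are free to list either allele first; the weight table
defines the orientation that matters. For each shared variant id the
dataset's allele pair is matched to the weight table's directly, as a
swap (dosage recoded 2−g), or on the opposite strand via
complementation (with or without swap). Palindromic A/T and C/G pairs
cannot be strand-resolved without external frequency information, so
the default policy drops them with a warning; `keep` trusts the file
strand. Variants matching neither way are dropped with a logged reason.
Variant identity is keyed on the variant id string (weight panels are
typically rsID-keyed), not position.

## Variant QC

Defaults: call rate ≥ 0.95, MAF ≥ 0.01, HWE exact p ≥ 1e-6, pairwise
LD r² ≤ 0.8 — conventional array-QC settings for case-control panels.
The HWE test is the exact conditional test: with the allele counts
fixed, every attainable heterozygote count h (same parity as the rare
allele count) has probability ∝ 2^h · n!/(n_rr! h! n_cc!), and the
p-value is the total mass of configurations no more likely than the one
observed — the standard probability-mass two-sided definition. The
implementation evaluates the distribution with log-gamma arithmetic and
counts ties with a 1e-10 relative slack; the test-suite verifies
agreement to 1e-12 with an exact integer-arithmetic enumeration over
the full grid of genotype triples with total ≤ 50. HWE is evaluated on
all samples by default with a controls-only switch (`VariantQC
(hwe_controls_only=True)`), since genuine risk variants can deviate in
cases.

LD pruning is greedy in input (genomic) order: a variant is dropped if
its r² — squared Pearson correlation of dosages over jointly observed
samples — with any previously kept variant on the same chromosome
exceeds the bound. Any kept set satisfying the pairwise bound would be
admissible; the greedy rule is fixed for reproducibility. The genotype
PCA mean-imputes missing dosages, standardizes columns, and extracts
top components by full SVD with the sign fixed so each component's
largest-magnitude loading is positive.

## Tertile risk models

Tertile boundaries are the nearest-rank empirical 1/3 and 2/3 quantiles
of the *pooled* score vector — both case cohorts plus the shared
controls — i.e. the order statistics at 0-based indices ⌊n/3⌋ and
⌊2n/3⌋. Samples strictly below a cut point fall in the lower group;
boundary ties all go up, which is deterministic and order-independent.
With distinct scores and 3 | n the split is exact (768 → 256/256/256).

Per-tertile odds ratios against T1 come from maximum-likelihood
logistic regression (statsmodels) on T2/T3 indicators plus any
adjustment covariates, with Wald 95% CIs exp(b ± 1.96·se). Separation
— plausible when a top tertile contains almost no controls — is
detected by runaway coefficients (|b| > 15) or exploded standard errors
and triggers, under the default `firth="auto"` policy, a bias-reduced
refit that maximizes the Jeffreys-penalized likelihood (Firth-type
modified score with hat-value correction); its estimates remain finite
under separation. The cumulative sensitivity/specificity columns and
the ordinal (3-level) AUROC make the table self-contained.

## AUROC and confidence intervals

The AUROC estimator is the tie-corrected Mann–Whitney statistic —
#(case > control) + ½·#(ties) over all case-control pairs — applied
identically to continuous scores and to ordinal grouped counts; the
midrank tie rule is what makes published tertile count tables exactly
recomputable. Confidence intervals use the DeLong structural-components
variance (sample variances of per-observation placement values) with a
normal approximation, truncated to [0,1]; a degenerate variance
(perfect or constant classifier) collapses the interval to the point
estimate with a warning. Displayed metrics round half-up to 3 decimals.

## Synthetic studies

`simulate_case_control` emulates a two-disease shared-control design:
31 independent panel variants (29 tagged `gwas`, β ~ |N(0.5, 0.2²)|;
2 tagged `reported`, β ~ |N(0.2, 0.1²)| — shapes chosen to mimic a
genome-wide-significant panel plus weaker literature variants), MAFs
uniform on [0.05, 0.5], genotypes in Hardy–Weinberg proportions,
cohort quotas 250 / 222 cases and 296 controls, and covariates (age
N(55, 15²) years; sex and four binary comorbidity/smoking flags with
prevalences 0.5 / 0.30 / 0.15 / 0.25 / 0.25). Disease status follows
the additive logistic liability logit P = α + Σβ_j g_ij + γ'x with
γ = 0.03 per year of age and 0.30–0.60 for the binary flags; covariate
confounding with the labels arises from these liability terms rather
than from label-conditional draws. The second disease shares a
configurable fraction (default 0.7) of the panel's effects and has zero
effect at the remaining variants, so cross-disease discrimination
interpolates between the discovery AUROC (fraction 1) and chance
(fraction 0). The intercept α is tuned by bisection on a 20,000-draw
reference population to a target case fraction (default 0.25), and
cohorts are filled by rejection sampling; controls are individuals with
neither disease, matching a CVD-free shared-control design. Under
case-control sampling the non-intercept logistic coefficients remain
consistent for the generative β, which is what makes parameter-recovery
experiments well-posed; the recovery experiment in the acceptance
script sets the shared fraction to 0 so that screening controls against
the second disease does not itself select on genotype.

A separate binormal helper (`simulate_normal_scores`) draws case and
control scores N(δ, 1) / N(0, 1), for which the population AUROC has
the closed form Φ(δ/√2) used in analytic calibration checks.

What the generator does **not** emulate: LD between panel variants
(sites are independent), genotyping batch/plate artifacts, non-additive
(dominance/epistatic) effects, age- or sex-specific effect
modification, and realistic covariate correlation structure. Passing
tests therefore demonstrate correctness of the pipeline's computations
and calibration under the stated generative model, not performance on
real arrays.

## Problem sizes

The test-suite and acceptance script choose desk-scale sizes: oracle
comparisons on 20–50-sample matrices, the study design at its native
768 samples, effect recovery on a single n = 20,000 draw (joint
logistic over all 31 variants plus covariates; mean signed bias and
mean absolute error both well under 0.05), and CI-coverage experiments
with 500–1000 replicates at n = 150–600. A published study's
continuous-score AUROCs, covariate-adjusted ORs and risk-allele count
distributions depend on its individual-level genotypes and covariates;
when those are not deposited, such values are checked only
qualitatively here (discovery > cross-disease validation AUROC for a
partially shared panel; monotone tertile ORs), never numerically.

## Known limitations

- Multi-allelic VCF records are rejected, not split; dosage (fractional)
  genotypes and reference-panel imputation are out of scope.
- Sample-level QC (per-sample call rate, heterozygosity, relatedness)
  is not implemented; inputs are assumed sample-clean.
- The ordinal AUROC CI uses the DeLong variance on grouped placements;
  published tables rarely state their CI method, so intervals are a
  documented convention rather than a claimed match.
- Cross-validation utilities are generic (sklearn-compatible
  estimators); no attempt is made to mirror any specific study's
  unreported CV scheme.
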