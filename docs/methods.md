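# Methods

## Scope and model family

The package analyses a single case-control stratum at a time: a binary
phenotype (1 = high-aggressive, 0 = low-aggressive disease), a matrix of
minor-allele dosages for ~11 biallelic polymorphisms, and three adjustment
covariates — age (years, untransformed), study site (0/1 indicator) and a
genetic-ancestry proportion in [0, 1]. All inference is by
maximum-likelihood logistic regression with Wald standard errors; every
fitted model, including interaction-only models, carries the three
covariates. Missing data are handled complete-case per fitted model: a
sample is dropped from a fit when any variable in *that* model is missing,
so the effective n (and therefore the BIC's ln(n)) can differ across
pairs.

## Genotype coding

Minor alleles are assigned within the analysed stratum: dosages are
re-oriented (g → 2−g) whenever the counted allele's frequency exceeds 0.5,
with an exact 0.5 tie broken toward the lexicographically smaller allele
label. This matters in practice — the same variant can have opposite
minor alleles in different ancestry groups — and it makes the operation
idempotent. Inheritance modes map dosage to a predictor: additive g,
dominant 1[g≥1], recessive 1[g=2]. The *reverse* risk direction is the
major-allele orientation of the same mode: 2−g for additive, the
complement indicator otherwise. A direction applies to a variant's coding
once, so in structures that keep a main effect the reversed coding enters
both the main-effect column and the product column. (The alternative
reading — reversing only the product term — was considered and rejected as
internally inconsistent; it would make the product term not the product of
the model's own main-effect codings.)

## The 45-pattern catalogue

Five mode combinations (AA, DD, DR, RD, RR; first letter = first variant)
× nine structure/direction variants: one `Full` (directions fixed at
original — reversing a direction inside a full model is an affine
reparametrisation with identical likelihood and BIC, which the test suite
verifies to 1e−8), two `M1_int` (direction of variant 1 varies), two
`M2_int`, four `int_only` (both directions vary). The inclusion of AA as
the fifth combination reflects that the additive-additive full model is
the conventional baseline for pairwise interaction testing; the published
description of the approach lists additive among the modes but prints only
D/R examples, so this is an inference, not a printed fact.

Per pair all 45 models are fit; a pattern is recorded as unfittable (with
a reason) when its product column is constant in the complete cases, the
design is rank-deficient, or the fit separates. Selection is minimum BIC
(−2ℓ + k·ln(n)); ties within 1e−9 break toward fewer parameters, then
catalogue order. Interaction-only codings can alias — different labels
inducing the same two-class partition of the 3×3 genotype grid produce
identical fits — so recovery claims are made about the induced partition,
not the label string, and the deterministic tie-break makes the reported
label reproducible. The pair's summary statistics (OR, 95% CI, p) always
come from the selected model's product term.

## Single-variant layer and multiplicity

Each variant is tested under the three modes; the reported result is the
mode with the smallest Wald p of the genotype term (ties: additive >
dominant > recessive). Modes whose coding is constant (e.g. recessive for
a rare variant with no minor homozygotes) are excluded with a logged
reason rather than allowed to fail silently. Because best-of-three-modes
selection inflates the per-variant type-I error above nominal (the suite
demonstrates this empirically), the Bonferroni correction divides by the
number of variants (0.05/11) and pairs (0.05/55), not variant-mode
combinations. Thresholds are rounded to 4 decimals only for display;
comparisons use exact values. Wald rather than likelihood-ratio p-values
are used throughout, matching the OR (95% CI) + p reporting convention.

## Bootstrap internal validation

B=500 replicates resample n individuals with replacement (unstratified by
default, matching plain resampling from the original data; a
case/control-stratified option exists). In each replicate the pair's
*previously selected* pattern is refit as a fixed hypothesis —
re-selecting among 45 models per replicate would mix model-selection
instability into the significance count — and each component variant's
p-value is the per-replicate best of its three modes. A replicate passes
the 3pRule when p_pair < 0.01 and p_pair is below both (default) or either
(configurable) component p-value; the two comparison rules are both
implemented because the methods wording ("and") and the results-table
footnotes ("any of the two") of the source study disagree. Degenerate
replicates (single-class outcome, constant coding, separation) count as
non-significant and are tallied. Final selection: original-data p_pair <
0.05 and significance percentage strictly greater than 65%.

## Synthetic cohorts

The generator emulates the two published strata. Genotypes are i.i.d.
Hardy–Weinberg draws, g ~ Binomial(2, MAF), at the published per-variant
MAFs; the EA profile generates its one strongly linked pair (r² = 0.86)
from the four-haplotype distribution implied by (p₁, p₂, D) with
D = r·√(p₁q₁p₂q₂), rejecting targets beyond the feasibility bound
|D| ≤ min(p₁(1−p₂), p₂(1−p₁)). All other variants are mutually
independent, reflecting the reported weak LD (r² < 0.3) elsewhere. Age is
normal, site Bernoulli, ancestry truncated-normal on [0, 1] — an
approximation: the real ancestry-proportion distribution is strongly
left-skewed with the mass near 1, and only its mean/SD were available.

Outcomes follow the logistic model above with a configurable generating
pattern and log-odds effects. Covariate effects default to zero (no
covariate coefficients were published); covariate *adjustment* is still
exercised in every fit, but the generator does not emulate confounding
unless asked. The intercept is calibrated by bisection so the marginal
(population-average) prevalence matches the stratum target to 1e−6 —
marginal rather than conditional because the published prevalences are
marginal. What a green test on these cohorts establishes is therefore
statistical correctness of the machinery (calibration, recovery,
selection behaviour) under HWE, independence and clean genotyping — not
robustness to population structure, genotyping error, missingness
patterns or covariate confounding, none of which are simulated.

## Numerical choices

- Logistic fits: statsmodels Newton with tol 1e−10 (needed for the 1e−8
  BIC-invariance guarantee), max 200 iterations. A fit is flagged
  non-converged when the optimiser says so, any |β̂| ≥ 30 (quasi-
  separation), or a standard error is non-finite; flagged fits never
  contribute estimates or BICs.
- Constant-predictor and rank checks run before fitting and raise typed
  errors; the scan converts them into per-pattern exclusion records.
- LD r² is the squared Pearson correlation of dosages (composite LD) with
  pairwise deletion; undefined cases (fewer than 2 complete pairs, zero
  variance) return NaN rather than raising.
- Genotype-distribution comparisons use the Pearson chi-square without
  continuity correction, collapsing categories empty in both groups.
- Intercept calibration brackets [−50, 50] and bisects on the prevalence
  gap (monotone, so always solvable).
- Seeds: every stochastic operation takes an explicit seed;
  `make_stratum_cohort` derives per-variant/per-stage substreams from a
  `SeedSequence`, so cohorts are bit-reproducible and adding an effect
  spec does not perturb the genotype draw.

## Clinical classifier

High aggressive: Gleason ≥ 8, or PSA > 20 ng/mL, or Gleason ≥ 7 with
stage T3–T4. Low: Gleason < 7 and stage T1–T2 and PSA < 10. All other
combinations — including the PSA band [10, 20] with low Gleason — are
intermediate, exactly as the boundaries are printed; no smoothing of the
undefined middle band is attempted. The pipeline's phenotype is the
high-vs-low contrast; intermediate cases are excluded upstream.

## Known limitations and source quirks

- The del/ins polymorphism is carried with chromosome "19" as printed in
  the source summary table even though the gene resides at 5q14.1; the
  metadata is stored as given and not corrected.
- Whether the source's r² was haplotype-based (EM) or dosage-based is
  unstated; dosage-based composite LD was chosen (no phase estimation is
  attempted anywhere).
- The ancestry covariate is one continuous proportion per stratum
  (European for EA, African for AA profiles); the source is ambiguous
  about which proportion enters its models.
- p-values of BIC-selected patterns are post-selection quantities: under
  the null their distribution is not uniform, which is why the validation
  layer exists. The suite records this behaviour; it does not assert
  uniformity.
- No imputation, no Hardy–Weinberg QC filtering, no 3-way interactions,
  and no genome-wide scaling work: the design targets candidate panels of
  tens of variants.
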