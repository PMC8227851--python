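# Methods

## The problem

Forensic DNA phenotyping predicts a donor's eye colour from a handful of
pigmentation SNPs. The dominant signal is rs12913832 (*HERC2*, in the
*OCA2* promoter): GG individuals are almost always blue-eyed, A-allele
carriers almost always brown-eyed. A small set of modifier variants in
*OCA2*, *TYRP1*, *TYR*, *SLC24A4*, *SLC45A2* and *IRF4* explains part of
the exceptions — notably two rare *OCA2* variants (rs121918166,
rs74653330) whose carriers tend to be blue-eyed even on an AG background.
This package implements, end to end, the quantitative phenotype handling,
the resampled variable-selection procedure, the LOOCV prediction models
and the forensic reporting layer that such a study uses, plus a synthetic
cohort generator so that every stage can be exercised and tested without
access to the original (undeposited) cohorts.

## Phenotype scale

The quantitative phenotype is the PIE-score r = (blue − brown)/(blue +
brown) over classified iris pixels, in [−1, 1]. Models operate on the
unbounded working scale y = logit(0.5 + 0.499·r) (natural log). The 0.499
factor confines the logit argument to [0.001, 0.999], so y(±1) = ±ln 999 ≈
±6.9068 and the map is exactly invertible; the inverse maps every real
into (−1, 1] ∪ {−1} (values beyond ±ln 999 clip to the endpoints).
Categorisation is fixed: two-category blue iff r > 0.2; three-category
blue iff r > 0.8, brown iff r < −0.5, intermediate on the closed interval
between. Boundaries are exact — no epsilon tolerance.

## Genotype coding

Calls are unordered allele pairs (indel alleles are full strings, e.g.
"TCT-"). Minor alleles are determined from the analysed cohort itself and
recorded, so an encoding is reproducible on other data; ties at frequency
0.5 break lexicographically. Codings: additive (minor-allele count 0/1/2),
dominant for rs12913832 (AA/AG → 0, GG → 1, defined by homozygosity for
the variant allele), carrier (any minor allele → 1), and combined (capped
sum of minor-allele counts over several rare variants, used for
rs121918166 + rs74653330 in the ranking stage). In the EC11 *prediction*
panel the two rare variants stay separate carrier variables: with dominant
rs12913832 and eight additive SNPs this is the only coding whose genotype
space has 2³·3⁸ = 52,488 combinations, matching the published space size.
Samples with any missing panel call are dropped by default (prediction
uses complete profiles); mean imputation is available behind a flag for
exploratory use.

## Synthetic cohorts

Genotypes are drawn per variant i.i.d. in Hardy–Weinberg proportions at
the packaged population frequencies (44 variants; discovery-set and
Norwegian-model-set columns). Variants are independent — no LD is
simulated, so LD-dependent behaviour (e.g. the *TYRP1* haploblock) is out
of scope of what passing tests demonstrate. Phenotypes follow a linear
model on the transformed scale,

    y = β₀ + Σ βⱼ gⱼ + Σ γⱼ g_hub·gⱼ + ε,   ε ~ N(0, σ²),  r = f⁻¹(y),

with the dominant rs12913832 variable as the interaction hub — exactly the
model family the selection stage fits, which makes parameter recovery a
meaningful test. Default effects (package constants, not biological
estimates): intercept −0.3, rs12913832 +5.4, combined rare-OCA2 carrier +4
with a −4 interaction on the GG background (so the rare variants matter
only for A-allele carriers, mirroring the blue-eyed-AG phenomenon), small
modifier effects of |β| 0.2–0.8 with signs per the modifier's reported
direction, σ = 1.8. They were calibrated once against coarse cohort
marginals — a two-category blue fraction near 60–70% (discovery
frequencies) and 72% (model frequencies), and two-category LOOCV accuracy
near 0.9 — and then frozen. Under these defaults the simulated category
fractions and LOOCV errors land close to the published cohort composition
and error magnitudes, which is a consistency check, not a fit.

One caveat the defaults expose: with weak modifiers, the richer panels do
not reliably beat the single-SNP model out of sample — the extra
coefficients cost more variance than their signal is worth, and the
published EC11 ≤ IrisPlex ≤ rs12913832 error ordering emerges reliably
only when modifier effects are substantial. The corresponding invariant is
therefore tested under a strong-modifier generator configuration.

## Variable selection

The cohort is split 100× (test suites scale this down to 20×) into 2/3
train / 1/3 test, redrawing any split that fixes a coded variant in
training (cap 10,000 redraws, then an error naming the variant). Per
split, seven models: for the quantitative and two-category systems a
lasso with main effects, a lasso adding all rs12913832×modifier
interactions (main effects always present — the hierarchical principle
holds by construction), and a CART tree; for the three-category system a
classification tree only. Lasso details follow glmnet conventions:
predictors standardised to unit SD, 100 log-spaced penalties down to
1e−4·λ_max, 10-fold CV, one-standard-error rule (largest penalty within
one SE of the minimum mean CV error), final refit on the full training
part. Raw importances are |standardised coefficient| (an interaction term
accrues to both partners; a flag restricts it to the non-hub partner) and
total impurity decrease for trees. Within each (split, model) cell,
importances are normalised to sum 1 (all-zero fits stay zero); the mean
over all cells ranks the variables, and the selection keeps those at or
above 0.3% mean importance.

Tree settings emulate rpart defaults: minsplit 20, maxdepth 30, and
cp 0.01 mapped to `min_impurity_decrease = 0.01 × root impurity` (rpart's
cp is relative to the root deviance). Surrogate-split importance is not
implemented; importances come from primary splits only, a documented
deviation from rpart.

### Numerical choices in the lasso path

The coordinate-descent solver (numba-compiled) uses warm starts along the
path, an active-set strategy with exact KKT rescans for feature admission,
and IRLS with a capped number of quadratic refits per penalty for the
binomial family. The convergence tolerance scales with the largest
coefficient magnitude because coefficients legitimately diverge under
separation at tiny penalties. The path terminates early once the deviance
is essentially saturated (<0.1% of the null deviance), stops improving
(<1e−4 of the null deviance per step, after the first 20 penalties), or
the support exceeds a dfmax of max(20, n/10) features; later penalties
reuse the last solution. These cuts only affect the deep overfitting tail
that the one-standard-error rule never selects; mid-path solutions agree
with independent solvers (sklearn coordinate descent / saga) to ~1e−6.
CV fold assignment is drawn from a per-replicate substream of the master
seed, so replicates are independent and individually reproducible.

## Prediction models

For a given panel and reporting system, fitted by maximum likelihood with
a fixed tiny L2 ridge (1e−6) on slopes (intercepts unpenalised):
quantitative — linear regression of y; two-category — binomial logistic
with blue = 1; three-category — multinomial logistic (full Newton,
gradient tolerance 1e−8, cap 200 iterations; the ridge guarantees a
unique finite optimum under the perfect separation that synthetic cohorts
can produce). The rs12913832-only three-category model is fit exactly as
specified despite its two-level predictor; it simply cannot call more than
two categories. LOOCV refits the model n times, each sample predicted by
the model trained on the other n − 1. Errors: quantitative — MSE on the
transformed scale (the scale the model fits; reported PIE predictions
pass through the inverse transform); two-category — mean −log p(truth);
three-category — mean Kullback–Leibler divergence from the one-hot truth,
equal to mean −log p̂(observed category). Probabilities are clipped to
[1e−12, 1 − 1e−12] before logs. Error aggregation uses means, which
matches the magnitude of published per-sample losses.

## Reporting

A categorical prediction is called as the argmax category (pmax) or, under
a threshold t ∈ {0.5, 0.7}, only when max p ≥ t — otherwise inconclusive;
exact argmax ties are inconclusive under every policy. Sensitivity and
specificity are one-vs-rest over conclusive calls (blue is the reference
class in two-category summaries); percent correct/incorrect/inconclusive
are over all samples and sum to 100 exactly. Genotype-space enumeration
takes the Cartesian product of coded levels (3 per additive/combined
variable, 2 per dominant/carrier) and, given a fitted model, reports
per-category counts, fractions and the maximum probability each category
attains anywhere in the space. The two-category likelihood ratio for a
genotype g is P(g | brown)/P(g | blue) from the cohort's conditional
genotype frequencies, optionally with add-0.5 smoothing; unsmoothed, a
zero denominator is an error rather than an infinite LR.

## Problem sizes used in the checks

The test suite and the acceptance script use desk-scale versions of the
study design: ranking runs 20 resampling splits (not 100) on 750–757
sample cohorts, the recovery check repeats this over 20 seeds, and LOOCV
runs at the study's n = 523. These sizes keep every property at
comfortable statistical resolution while the full suite completes in a
few minutes; the packaged `run_paper_like.yaml` config runs the full
100-split design.

## Known limitations

- No LD between simulated variants; pairwise r² estimation is composite
  (squared dosage correlation), not haplotype-based EM.
- The generator's effect sizes are synthetic calibration constants; none
  of the numeric outputs are estimates of the original study's models.
- Published quantities that depend on the unreleased cohorts (exact error
  values, sensitivities, importances) are reproduced in magnitude and
  ordering only; the two genotype-space counts are exact.
- The lasso path's deep tail is deliberately approximate (see above); it
  is never used by the one-standard-error selection.
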