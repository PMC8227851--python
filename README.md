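# ec11 — SNP-based eye-colour prediction

Forensic DNA phenotyping toolkit around the EC11 idea: predict a person's
eye colour from a small pigmentation SNP panel, with the whole analysis
chain as reusable, tested code — quantitative eye-colour scores, a
resampled multi-model variable-importance ranking for SNP selection,
leave-one-out cross-validated prediction models under three reporting
systems, and a forensic reporting layer (probability thresholds,
sensitivity/specificity tables, genotype-space enumeration, likelihood
ratios).

Who it is for: forensic geneticists and methods researchers who want to
rank candidate pigmentation variants, build and evaluate eye-colour
prediction models on their own reference cohorts, or study the behaviour
of threshold-based reporting policies — without the original study's
(undeposited) data, which a packaged synthetic-cohort generator stands in
for.

## The science in brief

Eye colour is measured as the PIE-score r = (blue − brown)/(blue + brown)
pixel counts of an iris photograph (1 = fully blue, −1 = fully brown),
modelled on the unbounded scale y = logit(0.5 + 0.499·r), and categorised
as blue/brown (threshold 0.2) or blue/intermediate/brown (0.8 and −0.5).
Genotypes are coded additively (minor-allele counts), with rs12913832
(*HERC2*) coded dominant (AA/AG → 0, GG → 1) and rare *OCA2* variants
carrier-coded. Variable selection repeats a 2/3–1/3 split 100 times and
fits seven models per split (gaussian/binomial lasso with and without
rs12913832 interactions, selected by 10-fold CV with the
one-standard-error rule, plus CART trees); standardised importances are
averaged across all split × model cells and variables above 0.3% mean
importance are kept. Prediction models are linear, binomial-logistic and
multinomial-logistic GLMs evaluated by LOOCV with MSE, log-loss and
Kullback–Leibler error. Reporting uses the most-probable category (pmax)
or probability thresholds (0.5 / 0.7) with inconclusive calls, and
two-category evidence weights LR = P(genotype | brown)/P(genotype | blue).

Built-in panels: `ec11` (11 SNPs), `irisplex6` (the 6 IrisPlex SNPs),
`rs12913832` (single SNP) and `discovery44` (the 44-variant ranking
panel), with published allele frequencies for two European populations.

## Worked example

```python
from ec11 import (
    simulate_cohort, paper_like_config, builtin_panel,
    loocv_predict, report, CallPolicy, enumerate_genotype_space,
)

# a synthetic stand-in for the 523-individual Norwegian model cohort
cohort = simulate_cohort(paper_like_config(523, seed=1, freq_set="model"))
panel = builtin_panel("ec11", freq_set="model")

res = loocv_predict(cohort, panel, "two_category")
print(f"two-category log-loss (LOOCV, n={res.n}): {res.error:.3f}")

tab = report(res, CallPolicy())           # pmax: always call the argmax
print(f"sensitivity (blue): {tab.sensitivity['blue']:.2f}, "
      f"specificity: {tab.specificity['blue']:.2f}, "
      f"correct: {tab.percent_correct:.0f}%")

space = enumerate_genotype_space(panel)
print(f"EC11 genotype space: {space.n_combinations} combinations")
```

prints

```
two-category log-loss (LOOCV, n=523): 0.220
sensitivity (blue): 0.94, specificity: 0.95, correct: 94%
EC11 genotype space: 52488 combinations
```

The log-loss is the mean −log probability the LOOCV model assigned to each
sample's true category (smaller is better; 0.69 would be coin-flipping).
Sensitivity/specificity take blue as the reference class under pmax calls.
The genotype space count is the number of distinct coded EC11 profiles
(2³·3⁸ — two-level dominant/carrier variables, three-level additive ones).

The same stages are available from the shell:

```
ec11 simulate --n 523 --seed 1 --freq-set model --out-prefix sim/
ec11 rank     --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
              --panel discovery44 --reps 100 --seed 17 --out importance.tsv
ec11 predict  --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
              --panel ec11 --system two_category --out loocv.tsv
ec11 report   --loocv loocv.tsv --system two_category --policy 0.7 --out report.json
ec11 run      --config src/ec11/data/run_paper_like.yaml   # whole pipeline
```

Genotype tables are plain TSV (`sample_id` + one column per rsid, calls
like `AG`, missing `./.`); phenotypes are `sample_id` + `pie_score`.

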