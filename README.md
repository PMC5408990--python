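# carrierprs

Polygenic risk scores (PRS) as modifiers of breast and ovarian cancer risk
in *BRCA1* and *BRCA2* mutation carriers.

Women carrying a pathogenic *BRCA1*/*BRCA2* mutation face high average
cancer risks, but common susceptibility variants spread those risks widely
across carriers. Quantifying that spread matters clinically: it can move
the age at which a carrier's ovarian-cancer risk justifies risk-reducing
surgery by several years. Analysing it is statistically delicate because
carrier cohorts are recruited through genetics clinics, which oversample
affected women; naive retrospective survival analysis is biased.

`carrierprs` implements the full analysis chain for this problem, for
statistical geneticists and epidemiologists working with carrier series:

- **PRS construction** (`carrierprs.prs`): the weighted allele-dosage sum
  `PRS_i = Σ_l β_l g_li` from a SNP weight table and genotype dosages
  (TSV or VCF), with allele harmonization, expected-dosage imputation,
  cohort standardization, and normal-quantile percentile categories.
- **Ascertainment weights** (`carrierprs.weighting`): weighted-cohort
  sampling weights so that, within age-band × gene strata, the weighted
  affected/unaffected mix matches the mix expected from the average
  carrier incidence `λ̄(t)` — affected records get `p/q`, unaffected
  `(1−p)/(1−q)`.
- **Weighted Cox engine** (`carrierprs.cox`): partial-likelihood
  Newton–Raphson on the age scale with delayed entry, sampling weights,
  study strata, Breslow/Efron ties, family-cluster robust (sandwich)
  covariance, and attained-age-varying covariates — powering per-SD fits,
  percentile-category models, PRS×age interactions, age-group effects,
  and pairwise SNP interaction scans.
- **Multiplicative polygenic model** (`carrierprs.polygenic`): hazard
  `λ(t|z) = λ0(t) e^{β(t) z}` with `z ~ N(0,1)` across carriers.
  Closed-form percentile-category hazard ratios
  `E[e^{βZ} | Z∈category] / E[e^{βZ} | Z∈reference]`, the baseline `λ0`
  constrained so the PRS-averaged incidence among survivors reproduces
  `λ̄(t)`, absolute cumulative risk (penetrance) curves by PRS percentile,
  and risk-threshold arithmetic (age at which a percentile reaches a risk
  level; fraction of carriers below a risk level at an age).
- **Discrimination** (`carrierprs.concordance`): Harrell's c for censored,
  left-truncated ages at diagnosis, with a bootstrap CI.
- **Synthetic cohorts** (`carrierprs.simulate`): clinic-ascertained
  retrospective carrier cohorts with Hardy–Weinberg genotypes, a
  proportional-hazards disease model with optionally age-decaying per-SD
  effect, shared family frailty, uniform censoring, and Bernoulli
  oversampling of affected carriers — so every stage is testable end to
  end without consortium data access.

## Worked example

Simulate a BRCA1 ovarian-cancer-like study (per-SD HR 1.28, clinic
oversampling of affected carriers), score the PRS, build weights, and fit:

```sh
carrierprs simulate --profile brca1_oc --n 600 --seed 11 \
    --out-cohort cohort.tsv --out-genotypes geno.tsv --out-truth truth.yaml \
    --out-weights-table wt.tsv --out-incidence inc.tsv
carrierprs prs --weights wt.tsv --genotypes geno.tsv --out prs.tsv
carrierprs weights --cohort cohort.tsv --incidence inc.tsv --out w.tsv
carrierprs fit --model continuous --cohort cohort.tsv --scores prs.tsv \
    --weights-file w.tsv --out fit.tsv
carrierprs cindex --cohort cohort.tsv --scores prs.tsv
carrierprs project --incidence inc.tsv --hr-per-sd 1.28 \
    --percentiles 1,50,99 --threshold-age 40 --threshold-risk 0.028 \
    --out proj.tsv
```

Output (seed 11):

```
term        estimate  se         robust_se  hr       ci_low   ci_high  p_one_sided  p_two_sided
prs_per_sd  0.194479  0.0801313  0.067391   1.21468  1.06438  1.3862   0.00195187   0.00390374

Harrell's c = 0.5432 (95% CI 0.5113 to 0.5787)

share of carriers below risk 0.028 at age 40: 0.4886
percentile 1: reaches risk 0.028 at age 42.4
percentile 50: reaches risk 0.028 at age 39.8
percentile 99: reaches risk 0.028 at age 30.3
```

Read: in this small cohort the weighted Cox fit estimates a hazard ratio
of 1.21 per SD of the PRS (true generating value 1.28; the 95% CI covers
it), the PRS discriminates onset ages modestly (c ≈ 0.54), and — taking
2.8% cumulative ovarian-cancer risk by age 40 as a reference level —
carriers at the 1st PRS percentile do not reach that risk until age ~42
while those at the 99th percentile reach it at ~30.

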