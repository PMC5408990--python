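# Methods

## The problem and the models

Carriers of pathogenic *BRCA1*/*BRCA2* variants are typically recruited
through cancer genetics clinics after a diagnosis in the family, so
affected carriers are oversampled relative to a population cohort.  The
package analyses the association between a polygenic score and age at
breast/ovarian cancer diagnosis in such series, and converts the fitted
associations into absolute risks. Three model layers are involved.

**PRS.** For individual *i*, `PRS_i = Σ_l β_l g_li`, where `g_li ∈ [0,2]`
is the effect-allele dosage and `β_l` the per-allele log risk ratio from a
published weight table.  Dosages counted on the opposite allele are
flipped (`2 − g`); strand-ambiguous A/T and C/G variants are matched by
identifier only and flagged, never complement-flipped. Missing dosages
are imputed at their Hardy–Weinberg expectation `2f_l` (standard scoring
practice; an individual missing more than 10% of variants is flagged).
Scores are standardized to mean 0, SD 1 (sample SD, ddof 1) over the full
analysis cohort, affected and unaffected together, unweighted; whether to
standardize within gene instead is an open choice — the package
standardizes per analysis cohort and records the moments used.
Percentile categories (0–5, …, 40–60 reference, …, 95–100) are bounded by
quantiles of `Normal(mean, SD²)` fitted to the cohort rather than
empirical quantiles, so category membership is invariant to affine
transformation of the raw score; an empirical-quantile mode exists behind
a flag.

**Weighted-cohort Cox regression.** Age is the time scale, with delayed
entry at `age_entry` (default 18) and age at diagnosis/censoring as exit.
The weighted partial likelihood (Breslow ties; Efron behind a flag) is
maximized by Newton–Raphson.  Sampling weights correct the status-based
oversampling; they are treated as fixed constants, with a cluster
sandwich covariance (clusters = families) covering both weighting and
within-family dependence.  One-sided p-values (`1 − Φ(coef/robust SE)`)
are reported alongside two-sided ones; the directional hypothesis — higher
PRS, higher risk — applies to the continuous per-SD terms, and all other
tests are read two-sided.

Weights are built within strata of 5-year age bands (18–80, open top
band) crossed with gene. With expected affected proportion `p` and
observed proportion `q`, affected records receive `p/q` and unaffected
`(1−p)/(1−q)`, which reproduces `p` exactly in every stratum; degenerate
strata (q ∈ {0,1}) are pooled with the nearest band until mixed, weights
are renormalized to sum to the cohort size and capped at 50 (logged when
triggered) so a single record cannot dominate a small cohort.

Two constructions of `p` are provided, and the choice matters:

- `method="cumulative-risk"`: the classic rule, `p = F̄(band midpoint)`
  with `F̄(a) = 1 − exp(−∫λ̄)` the average-carrier cumulative risk. It is
  the right expectation when a carrier's recorded age is, in effect, a
  current age under cross-sectional sampling.
- `method="calibrated"` (default): under sampling that thins records by
  disease status only — the design the synthetic cohorts implement — the
  observation-age distribution *within* each status group is undistorted,
  and only the overall affected/unaffected balance is wrong.  The correct
  expected proportions are then the observed per-band counts rescaled by
  one common factor `ρ`, chosen so that the overall weighted affected
  fraction equals the incidence-implied pre-ascertainment fraction
  `π = P(T ≤ C)`.  `π` is estimated from the unaffected records alone
  (their censoring ages `c_j` identify the censoring distribution up to
  the survival tilt), as `π̂ = Σ odds(c_j) / Σ (1 + odds(c_j))` with
  `odds(a) = F̄(a)/(1 − F̄(a))`; this estimator is invariant to the
  thinning itself.  The midpoint rule applied to a status-thinned design
  is badly miscalibrated — affected records observed at age *a* arise at
  rate `f̄(a)(1−G(a))` while unaffected arise at `g(a)S̄(a)`, which is not
  the `F̄(a) : 1−F̄(a)` split — and in simulation it attenuates a true
  per-SD HR of 1.27 to ≈1.16, whereas the calibrated weights recover it.

**Multiplicative polygenic model.** `λ(t|z) = λ0(t) e^{β(t) z}` with
`z ~ N(0,1)` across carriers, so relative risk is lognormal.  Theoretical
percentile-category hazard ratios use the closed form
`E[e^{βZ}; a<Z<b] = e^{β²/2} (Φ(b−β) − Φ(a−β))`; these are no-depletion
baselines — in survival data the realized late-age category contrasts are
attenuated as high-z carriers leave the risk set, which is asserted as an
ordering in the tests.  For absolute risks, `λ0` is pinned down by the
marginal-incidence constraint: the PRS-averaged incidence among survivors
must reproduce the known average carrier incidence `λ̄(t)` (an input
file, never a built-in constant — the published baselines belong to the
external literature). Risk at percentile `p` is
`F(t|z_p) = 1 − exp(−∫ λ0 e^{β z_p})` with `z_p = Φ⁻¹(p/100)` (the
point-quantile convention; a category-mean mode exists for comparisons
against fitted category HRs). Threshold arithmetic inverts these curves:
the age at which `F(t|z_p)` crosses a risk level (linear interpolation on
the grid, `+inf` sentinel when unattained) and the carrier fraction below
a risk level at an age (`Φ(z*)` with `z*` found by bisection, since `F`
is monotone in `z`).

**Harrell's c.** A pair is comparable when one member is diagnosed at an
age at which the other is still under observation (later exit, earlier
entry); c is the fraction of comparable pairs in which the earlier
diagnosis carries the higher score, ties counting ½. Optional sampling
weights enter as `w_i w_j`; both weighted and unweighted modes are
reported since the published analyses do not state which was used. The CI
is a 200-replicate individual-level bootstrap with a fixed seed (an
analytic variance was deliberately not substituted: the bootstrap also
covers the weighted mode).

## The synthetic-cohort generator

The generator emulates a clinic-ascertained retrospective carrier series:

- genotypes `Binomial(2, f_l)` at unlinked SNPs (defaults: K = 50,
  frequencies Uniform(0.1, 0.9), per-allele log risk ratios
  Normal(0, 0.08²) — the scale of published susceptibility-SNP effects);
- the latent PRS standardized by its Hardy–Weinberg population moments
  (`mean Σ2fβ`, `variance Σ2f(1−f)β²`), so the generating per-SD effect is
  defined against the population SD while the analysis pipeline
  re-standardizes by the realized cohort SD (an `O(β²)` difference,
  absorbed by Monte-Carlo tolerances);
- event ages by exact inverse-CDF sampling on the piecewise-constant
  hazard `λ0(t) e^{β(t) z}` (no numeric root finding, so closed-form
  oracle checks apply), with the age-varying effect
  `β(t) = β_0 + t·log(decay)` evaluated at interval midpoints;
- censoring ages Uniform(25, 80); optional shared lognormal family
  frailty (configurable family size; default size 1, i.e. independent —
  the frailty exists solely to exercise the cluster-robust variance);
- Bernoulli retention by status (affected kept with probability 1.0,
  unaffected 0.4 by default) until the target size is reached, with an
  explicit failure after a retry cap.

Four built-in incidence profiles provide gene/cancer-shaped average-risk
curves (synthetic calibrations, not published penetrance tables): BRCA1
and BRCA2 breast-cancer-like curves reaching ≈70%/67% cumulative risk by
age 80, and ovarian-cancer-like curves reaching ≈45%/17%, the BRCA1
ovarian curve pinned to 2.8% cumulative risk by age 40.  The marginal
incidence implied by a generating model (`marginal_incidence`) is the
curve the weights are built from, closing the loop between generator and
analysis.

What the generator does **not** emulate: linkage disequilibrium,
population stratification, genotyping error, family-history-based
(rather than status-based) ascertainment, competing mortality, and
risk-reducing interventions. Passing tests therefore demonstrate that the
estimators recover the parameters of this idealized design, not that the
weighting removes every bias present in real consortium data — in
particular, the real sampling mechanism is family-based and richer than
Bernoulli thinning.

## Numerical choices

- Newton–Raphson to an absolute gradient max-norm below 1e-8 (at most 100
  iterations, step-halving on likelihood decrease).  Columns are scaled
  internally to unit SD (age-interaction columns additionally by the
  transform's magnitude at the mean event age) so the stopping rule is
  scale-free; coefficients and covariances are mapped back exactly.
  Monotone likelihood (separation) is reported when a standardized
  coefficient exceeds 10.
- Time-fixed designs use an `O(n log n)` delayed-entry risk-set
  accumulation (suffix sums over exit- and entry-sorted orders);
  age-varying designs evaluate covariates at each event age in a
  per-event-time loop. The two paths agree to 1e-8 on constant
  transforms (tested).
- Efron ties are available through the per-event-time path; robust score
  residuals always use the Breslow decomposition (ages are continuous in
  every intended use, so tied-event corrections are a refinement of the
  point estimates, not the variance).
- The constrained baseline is solved interval by interval on a 1-year
  grid (the resolution of published penetrance tables): each `λ0_j` is a
  monotone one-dimensional root (bracketed Newton, relative tolerance
  1e-12) making the PRS-marginalized survival — a 64-node Gauss–Hermite
  quadrature over `z` — match the marginal survival at the next grid age.
  Solving the discrete conservation identity directly (rather than a
  pointwise hazard-ratio fixed point) makes marginal-risk conservation
  exact by construction, which the property tests assert at 1e-6.
- Percentile category boundaries, `z_p`, and threshold shares use scipy's
  normal distribution; bisection tolerances are 1e-10.
- Harrell's c loops over events with vectorized comparable-pair masks
  (`O(events × n)`), exact against the `O(n²)` oracle.

## Validation design and problem sizes

The published per-SD hazard ratios cannot be re-estimated from data (the
consortium genotypes are not public), so they are validated as parameter
recovery: cohorts are generated with the published value as the
generating effect, and the replicate-mean pipeline estimate must return
it within three Monte-Carlo standard errors of the replicate mean.
`scripts/acceptance.py` runs 30 replicates of n = 4,000 carriers per
target (40 × 4,000 for the low-event ovarian configuration, 15 × 4,000
for the time-varying interaction fit), sizes chosen to give Monte-Carlo
SEs of ~0.005–0.015 on the HR scale while the whole script stays within a
few minutes on a single CPU; recovery is within ~1% of the generating
values.  Rare-outcome configurations scale the baseline hazard so the
post-ascertainment affected fraction hits the target (~15%, and ~7.5% for
the few-hundred-events design), with the required scale found by
quadrature over the censoring distribution rather than trial simulation.

Absolute-risk projections are validated by structural properties rather
than by published numbers: the published risk curves rest on external
penetrance estimates and anchoring choices that are not recoverable from
the association results alone, so numeric equality is deliberately not
claimed. The properties — exact conservation, β = 0 degeneracy, the
small-risk limit `λ0 ≈ λ̄ e^{−β²/2}` (within 2% below 3% cumulative
risk), Monte-Carlo agreement of category HRs, and ordering of percentile
risks against a brute-force simulation — pin the machinery down instead.

## Known limitations

- The calibrated weighting assumes oversampling depends on status only;
  ascertainment correlated with age or family history within status would
  need the richer (e.g. kin-cohort or retrospective-likelihood) machinery
  that is out of scope here.
- Weights are treated as known constants; the sandwich covariance absorbs
  but does not remove the extra variability of estimating `π̂`.
- The percentile-category model and the theoretical category HRs ignore
  PRS-distribution depletion over age; their agreement degrades at high
  cumulative risks and late ages (asserted only as an ordering).
- No competing-risk adjustment: projected cumulative risks are
  net risks under the fitted hazard, not real-world probabilities in the
  presence of mortality and prophylactic surgery.
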