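# Methods

## Scope and model

`cardiogrs` implements a case-control analysis of multilocus genetic risk
scores (GRS) for coronary heart disease (CHD), built around a 19-SNP panel
of variants associated with CHD in white populations, and a comparison of
two populations with very different risk-allele frequencies (RAFs): an
Afro-Caribbean sample and a white, men-only sample of NPHSII type. The
package covers five linked pieces:

1. **Scores.** The unweighted GRS of an individual is the count of risk
   alleles over the panel, `GRS = Σ_i g_i` with dosage `g_i ∈ {0,1,2}`.
   The weighted GRS is `Σ_i w_i g_i` with `w_i` a per-SNP log-odds
   coefficient. The bundled panel ships with `w_i = ln(OR_i)` from the
   published per-allele odds ratios; the external meta-analysis β values
   used by the original study are not public, so weights are overridable
   (`SnpPanel.with_weights`) and weighted-score *means* from this default
   are not expected to equal any externally printed weighted means. A
   14-SNP sub-score excludes the five lowest-effect SNPs (published
   OR ≤ 1.04); membership is an explicit fixture flag.
2. **QC.** Per-SNP call rate, RAF, and the 1-df Pearson χ² test of
   Hardy-Weinberg equilibrium (HWE) on genotype counts. A Levene-Haldane
   exact test is available for the three panel SNPs with RAF ≤ 0.01,
   where the χ² approximation is anti-conservative. Cross-population RAF
   comparison is the allelic 2×2 Pearson χ² with allele counts
   reconstructed from (possibly rounded) frequencies by nearest-integer
   rounding; P values computed from rounded published frequencies are
   therefore approximate.
3. **Association.** Maximum-likelihood logistic regression
   (statsmodels) of CHD on the GRS and the traditional cardiovascular
   risk factors (TCRFs: age, sex, hypertension, diabetes,
   hypercholesterolemia, smoking), with Wald standard errors, 95% CIs
   `exp(β ± 1.96·se)` and two-sided Wald P — matching the symmetric-CI
   style of standard epidemiological reporting. GRS ORs are expressed per
   SD; the SD divisor defaults to the whole analysis sample's SD (the
   choice is exposed because published reports often leave it implicit).
   Quintile analysis cuts the score at the 20/40/60/80 percentiles of the
   whole sample — integer scores tie heavily, and ties on a cut point go
   to the lower bin — and fits Q2–Q5 dummies against Q1 with the same
   covariates. Whole-sample (rather than control-only) quantiles are
   deliberate: with cases enriched at high scores they produce the
   asymmetric control shares (large in Q1, small in Q5) characteristic of
   this design.
4. **Discrimination.** AUC by the midrank Mann-Whitney estimator (ties
   half-credited), standard error and the paired two-model test by
   DeLong's structural-components method, with a stratified paired
   bootstrap as a cross-check. No pre-installed library provides the
   DeLong test, so it is implemented here and validated against brute
   force pairwise concordance, sklearn's point estimate, the bootstrap,
   and a null-calibration study.
5. **Projection.** Converting a between-population difference in mean
   GRS, Δ = mean_b − mean_a, into an expected relative risk reduction for
   the lower-scoring population. Two estimands are always reported side
   by side because the published recipe for this step is underdetermined:
   - *odds scaling*: `1 − exp(−β·Δ)` with β the per-allele log-odds
     (closed form, exact on the odds scale);
   - *standardization*: `1 − E[p(g−Δ)]/E[p(g)]` averaged over the
     reference population — its individuals when a fitted model is
     supplied, otherwise a Normal(mean_b, sd) score distribution
     integrated by 64-node Gauss-Hermite quadrature with a stated
     baseline risk (default 0.10, a typical cumulative CHD risk for
     middle-aged men over long follow-up).
   The two agree as baseline risk → 0 and diverge (standardization
   smaller) at higher risk. On the published men-only inputs both fall in
   0.46–0.59, bracketing the published 54% (GRS19) and 44% (GRS14).

## Synthetic cohorts: what they emulate

No individual-level data are deposited for either study population, so
the pipeline is driven by a generator that reproduces the *statistical
structure* the analysis assumes:

- **Genotypes** i.i.d. Binomial(2, RAF) per SNP — HWE with no linkage
  disequilibrium, justified by the panel's loci lying in distinct
  genomic regions. RAF defaults are the bundled published control
  frequencies of each population.
- **Covariates** drawn independently: binary TCRFs at the published
  control prevalences (hypertension 30.1%, diabetes 14.8%,
  hypercholesterolemia 15.0%, smoking 13.4%; male fraction 43.7%), age
  Normal(51.66, 13.54²) truncated to [18, 100] years, BMI
  Normal(27.15, 5.62²) kg/m² with obesity = BMI ≥ 30. No TCRF
  correlation structure is imposed (none is published); a correlated
  generator would be a straightforward extension.
- **Disease** Bernoulli with logit `α + Σβ_j x_j + γ·GRS`. Covariate
  log-odds default to the published adjusted ORs (age 1.06/y, male 3.09,
  hypertension 4.30, diabetes 2.13, hypercholesterolemia 3.45, smoking
  3.06). γ is calibrated so the per-SD OR equals a target (1.40 for the
  Afro-Caribbean conditions) using the closed-form HWE SD
  `sqrt(Σ 2p_i(1−p_i))` ≈ 2.13 at those RAFs. The intercept α is set by
  Brent root-finding so the realized superpopulation prevalence equals
  the target to 1e-6. The population lifetime-ish CHD prevalence is not
  published for either sample; 0.10 is used, a conventional figure for
  middle-aged adults, and results of interest (ORs, AUC differences) are
  insensitive to it by the usual case-control argument.
- **Ascertainment**: a superpopulation of 3× the implied minimum size is
  generated, then the requested numbers of cases and controls (178/359
  Afro-Caribbean; 146/1214 white men) are drawn without replacement —
  mirroring a clinic-cases plus community-controls design and preserving
  odds ratios but not absolute risks.
- **Missingness** is missing-completely-at-random at a configurable
  per-entry rate (the published per-SNP call rates, 94–98%, correspond to
  rates of 0.02–0.06); complete-case filtering then drops any individual
  with a missing genotype or TCRF, as the original analysis did.

All randomness descends from one integer seed through
`numpy.random.SeedSequence`; identical config + seed reproduces cohorts,
and the full pipeline's report tables, byte for byte.

What passing tests on these cohorts does **not** show: robustness to
linkage disequilibrium between panel SNPs and causal variants (the very
mechanism suspected of degrading transferred weights across ancestries),
correlated risk factors, informative missingness, age-dependent
ascertainment, or population structure. The generator is a verification
harness for the analysis code and a power/design tool, not a model of
Afro-Caribbean genetic epidemiology.

## Numerical choices

- Logistic fits: statsmodels Newton/IRLS, convergence required (a
  non-converged fit raises rather than returning silently); complete
  separation and rank deficiency are detected up front with the offending
  columns named. Verified against an independent hand-written IRLS oracle
  to 1e-6 on random datasets, and against the exact 2×2 cross-product OR
  for a single binary predictor.
- HWE χ²: monomorphic SNPs are defined in equilibrium (χ² = 0, P = 1)
  and logged. The test is invariant to which allele is labelled "risk".
- 2×2 comparisons reconstructing counts from rounded frequencies round to
  the nearest integer allele count.
- Quintile ties: `searchsorted(edges, v, side="left")`, i.e. a value
  equal to a cut point falls in the lower bin; if ties collapse a bin the
  analysis refuses with a suggestion to use fewer bins.
- Woolf CI for 2×2 ORs; zero cells raise unless the Haldane-Anscombe
  0.5 correction is explicitly requested.
- Student's pooled-variance t by default (Welch behind a flag), accepting
  either raw vectors or (mean, sd, n) summaries so published summary
  tables can be tested directly.
- Intercept calibration tolerance 1e-6 on prevalence; Gauss-Hermite order
  64 for the summary-based standardization integral (exact for this
  smooth integrand to well below reporting precision).

## Problem sizes used by the test-suite and acceptance script

Simulation-backed checks run at the study's own sizes (178/359 and
146/1214) or at 10⁵ for closed-form-limit checks; replicate counts are
200 for parameter-recovery coverage, 1000 for test-size calibration, 500
for DeLong null calibration, and 25 replicate cohorts for estimating
expected simulated GRS means. These sizes keep every Monte-Carlo margin
several standard errors away from its pass threshold.

## Known limitations

- Default weights are `ln(published OR)`, not the original meta-analysis
  β values; weighted-GRS means are comparable only within runs.
- The per-SNP case-control P values published for individual SNPs are not
  reproduced by the allelic χ² on published frequencies; their generating
  model is unspecified and is not guessed at.
- VCF support is GT-only, bi-allelic, rsID-matched; no liftover, strand
  flipping, or proxy-SNP substitution.
- The projection treats the transferred per-SD OR as causal and constant
  across populations — the same strong assumption the published
  calculation makes; it is a what-if computation, not an estimate of an
  identified causal parameter.
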