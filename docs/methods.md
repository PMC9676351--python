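# Methods

## Overview

`metabrisk` implements a serum NMR-metabolomic analysis for prognosis in
early breast cancer (eBC).  Bucketed 1H NMR spectra are used to train a
random-forest (RF) classifier separating relapse-free early-stage sera from
metastatic (aBC) sera; the fraction of trees voting a sample "metastatic"
is read as a continuous risk score, dichotomized into high/low metabolomic
risk, and evaluated against the recurrence-free interval (RFI) with
Kaplan-Meier, log-rank and Cox models.  Because no patient-level data are
distributable, the package ships a synthetic cohort generator that
reproduces the study design; all regime-level tests run against it.

## Spectral preprocessing

* **Bucketing.** Each spectrum is integrated (trapezoid rule, via the
  cumulative integral evaluated at bucket edges) over half-open `[lo, hi)`
  buckets of 0.02 ppm tiling 0.2-10.0 ppm: 490 buckets.  Columns are kept
  in descending-ppm display order.  The half-open grid convention is a
  package choice; it makes the water window an exact number of buckets.
* **Water exclusion.** Buckets contained in 4.42-5.10 ppm (34 buckets) are
  dropped, leaving 456 features.  Exclusion edges must lie on the bucket
  grid; partial-bucket removal is refused rather than approximated.
* **PQN.** Each row is total-area normalized, then divided by the median
  over buckets of the row/reference quotient.  The default reference is
  the median spectrum of the relapse-free early training samples
  (configurable); buckets with zero reference are excluded from the
  quotient median with a logged count.  PQN is scale-invariant per row, so
  per-sample dilution cancels exactly.
* **Drift removal.** Spectra accumulated over a decade carry slow
  instrumental trends.  Per bucket, values are regressed on days since the
  earliest sample (ordinary least squares, linear term only) and replaced
  by residual + bucket mean, preserving bucket means exactly and making
  the operation idempotent.  A first-order model in time is the package's
  choice; higher-order or covariate-adjusted versions were out of scope.

## Random-forest risk score

* **Split.** Training = all relapse-free early patients + all advanced
  patients; validation = all early patients who relapsed.  The advanced
  class is the positive class.
* **Ensemble.** 500 unpruned CART trees, each on an independent bootstrap
  of the training rows, floor(sqrt(p)) = 21 candidate features per split
  (p = 456).  Bagging and bootstrap membership are explicit in the package
  (the tree inducer is scikit-learn's) so out-of-bag (OOB) bookkeeping is
  exact per sample and per tree.
* **Score.** For validation or external samples the score is the fraction
  of all trees voting metastatic; for training samples only OOB trees are
  eligible, and a training sample with zero OOB trees raises rather than
  silently using in-bag votes.  Scores at or above the threshold define
  the high-risk class (ties go to high).  `classify_risk` defaults to the
  0.5 majority vote, but the pipeline's default operating point is the
  *training prevalence* of the metastatic class (27/138 ≈ 0.196): under
  the ~4:1 imbalance the vote fractions of every group are compressed
  toward the majority class, and the majority cut would leave the
  high-risk group nearly empty, whereas the prevalence cut places roughly
  40% of early patients in the high-risk class with ~80% sensitivity —
  the operating regime this analysis is designed around.
* **Performance.** Sensitivity/specificity/accuracy come from the
  thresholded OOB confusion matrix of the training set (resubstitution
  votes would be near-perfect and meaningless); AUC is the Mann-Whitney
  probability that a random metastatic sample outscores a random early
  sample, ties counting one half.
* **Permutation test.** Training labels are shuffled, the forest refit,
  and the OOB statistic (accuracy by default; AUC available) recomputed;
  p = (1 + #{permuted >= observed}) / (1 + n_perm) with default
  n_perm = 99, so the smallest attainable p is 0.01.

## Metabolite analysis

28 metabolites are quantified as trapezoidal integrals over literature
chemical-shift windows (`metabrisk.regions`); nine carry configured stage
effects (3-hydroxybutyrate, citrate, N,N-dimethylglycine, phenylalanine up
in advanced disease; leucine, isoleucine, valine, acetate, histidine
down).  Each metabolite gets its own logistic model of stage
(relapse-free-early vs metastatic; relapsed early patients excluded) on
the z-scored concentration plus acquisition time in years since the
earliest sample; Wald p-values on the concentration term are
Benjamini-Hochberg adjusted across the panel at alpha = 0.05.  Degenerate
time covariates (a single acquisition date) are dropped; non-converged or
separated fits are flagged and excluded from the BH family with a warning.

## Survival analysis

RFI counts recurrence as the event; BC-related death requires a prior
relapse (and therefore never precedes recurrence), death without relapse
censors at death, and everyone else is censored at last follow-up.
Recurrence-only, overall survival and BC-specific endpoints use the same
record builder.  Kaplan-Meier (Greenwood variance), log-rank and Cox
(Efron tie handling, Wald 95% CIs) are delegated to lifelines behind the
module interface; every one of them is cross-checked in the tests against
hand or simulation oracles.  Cox reference levels are low risk, T1, N0,
luminal, G1; the multivariate model is risk class + T + N + subtype.
Subgroup analyses fit high-vs-low within each stratum level and report
levels with a single risk class or zero events as inestimable.

## Synthetic cohort generator

The generator emulates the study design, not any patient's data:

* **Sizes and covariates.** 140 eBC (29 relapsed) + 27 aBC by default;
  subtype mixes 77/10/13% (eBC) and 48/30/22% (aBC); T, N and grade
  frequencies from the published cohort table; acquisition dates uniform
  over Nov 2008 - Aug 2018.
* **Latent metastatic likeness.** Beta-distributed in [0, 1] with group
  means 0.80 (aBC), 0.55 (relapsed eBC), 0.30 (relapse-free eBC) and
  concentration 10; the relapse hazard is
  `baseline_hazard * exp(hazard_log_ratio * latent)` with defaults 0.03/yr
  and log-ratio 2.
* **Outcomes.** The relapsed count is pinned by design (it is an observed
  quantity in the emulated study), so relapse times are drawn from the
  latent-scaled exponential hazard conditioned on preceding follow-up
  (truncated inverse-CDF).  The unconditional sampler
  (`sample_event_times`) is public and is what the survival-construction
  checks exercise.  Follow-up is uniform over 8-11 years (median ~9.5 y)
  with a small random-censoring rate; 85% of relapsers die of disease
  after an exponential gap, others face a background death rate of
  0.035/yr, and a BC-related death always follows relapse.
* **Spectra.** Unit-area Lorentzian lines (width 0.004 ppm, an NMR-typical
  line shape with analytic area) centred in each metabolite's windows, on
  a uniform 0.001 ppm grid (fine enough that bucket integrals are
  grid-insensitive well below 0.1%); a broad Gaussian-hump macromolecule
  baseline; per-patient log-normal dilution (sd 0.15, removed by PQN) and
  baseline amplitude (sd 0.20); grid-point Gaussian noise (sd 0.05);
  additive linear drift of 3e-5 intensity/day so the decade-total drift is
  a modest fraction of baseline intensity.  CPMG attenuates the baseline
  (x0.15) and diffusion editing attenuates sharp lines (x0.25),
  caricaturing the pulse sequences' molecular-weight selectivity.
* **Effect sizes.** Stage effects are |log FC| = 0.30 for advanced disease
  and half that for relapsed early patients (zero for phenylalanine and
  acetate, whose advanced-stage trend does not carry over to relapse),
  against per-metabolite biological log-normal variation of sd 0.40.
  These values are the package's own choice of a plausible serum-NMR
  regime — the emulated study reports directions, not magnitudes — and
  they place the stage classifier's AUC around 0.80, the regime the study
  observed.  A single `effect_scale` knob multiplies every effect (0 gives
  an exactly null cohort).

**What the generator does not emulate:** real metabolite covariance and
lipoprotein structure, peak overlap and shift variation, baseline
distortions, multi-center batch structure, comorbidity- and
medication-driven metabolic heterogeneity of an elderly population.
Passing regime tests therefore show the pipeline recovers the structure it
assumes, not that the signature generalizes to real sera.

## Numerical and design choices

* Bucket integrals use the cumulative trapezoid evaluated at edges, so the
  sum of buckets equals the integral over the retained range to rounding.
* Determinism: one integer seed drives cohort generation, bootstrap
  resampling, tree randomness and permutations; identical config + seed
  gives byte-identical CSV reports (output paths are excluded from the
  config hash).
* Degenerate inputs fail loudly: spectra not covering the bucket range,
  misaligned exclusion windows, all-zero sample rows, single-class truth,
  zero-OOB training samples, empty strata.
* Problem sizes in the test suite are the package's own scaling choices:
  regime checks use 20 replicate full-size cohorts with 200-tree forests
  (AUC is insensitive to tree count beyond ~100); permutation type-I
  calibration uses 100 replicates of 19 permutations with the continuous
  OOB-AUC statistic (the discrete accuracy statistic ties too coarsely at
  small n_perm); the exhaustive KM oracle covers all 1024 event/censor
  patterns of 10 subjects plus tied-time grids.

## Known limitations

* The published headline numbers (AUC 0.79/0.78/0.81, sensitivity 81%,
  HR ~3.4) are properties of an unavailable patient cohort; the package
  reproduces the *procedure* and a synthetic regime of comparable
  difficulty, not those exact values.
* The drift model is linear in time only; the logistic models assume
  independent metabolites (no multivariate shrinkage); the permutation
  scheme permutes labels only.
* The luminal-only classifier of the emulated analysis is a configuration
  variant (filter the cohort before `build_split`), not a separate code
  path, and is not exercised by default.
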