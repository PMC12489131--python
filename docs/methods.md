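# Methods

This note records the statistical model, the defaults and why they were
chosen, the synthetic study design used throughout the tests, and the
numerical conventions. It is the package's own account of its science;
every number quoted here is computed by the test suite or the acceptance
script, not asserted from memory.

## Model and procedure

The pipeline consumes per-subject rows of six standardized features —
three cognitive factor scores (VA, EFPS, MEM) and three behavioral scales
(internalizing, externalizing, stress) — plus covariates, optional binary
diagnoses, optional environmental predictors, and a timepoint label.

1. **Harmonization** removes between-cohort location/scale differences by
   z-scoring each feature within each cohort. This is the minimal method
   consistent with post-harmonization summaries of mean ≈ 0 / sd ≈ 1 per
   cohort; an empirical-Bayes batch-adjustment backend could be added
   behind the same interface without changing callers. Harmonizing twice
   is the identity (within 1e-10), which the suite asserts.
2. **Residualization** replaces each feature by its least-squares residual
   on intercept + covariates (age, sex, ethnicity, handedness;
   categoricals treatment-coded against the most frequent level), then
   re-standardizes. Collinear covariate columns are dropped via pivoted QR
   with a warning rather than failing. A feature that is entirely missing
   in a table is passed through untouched when `allow_missing_feature` is
   set — the pattern for a scale absent in one cohort — and filled later
   by imputation.
3. **KNN imputation** fills a missing target scale with the unweighted
   mean of its k = 5 nearest donors (Euclidean distance over the
   remaining standardized features). k = 5 and the unweighted mean are
   package defaults; only the model family is dictated by the method.
   Donors may come from pooled cohorts, which is how a cohort lacking the
   scale wholesale borrows information.
4. **Fuzzy C-means** with fuzzifier m = 2, tolerance 1e-6 on the maximal
   membership change, at most 1000 iterations, best of 10 seeded restarts
   by the objective J. J is asserted non-increasing at every iteration.
   k is selected over 2..10 by the mean silhouette of the argmax-hardened
   partition (a candidate producing an empty hardened profile scores
   −inf). Fitting is Euclidean; Mahalanobis geometry enters *after*
   convergence through membership-weighted (fuzzy) covariance matrices,
   ridge-regularized by εI with ε = 1e-6·trace(Σ)/p to guarantee positive
   definiteness. Final and predicted memberships use the Mahalanobis
   membership formula; a zero distance makes the row an indicator (ties
   among zero distances split equally). A Gustafson–Kessel-style fit (i.e.
   Mahalanobis distances inside the alternating optimization) would be a
   natural alternative backend; the two-stage design was chosen because
   fitting and membership computation are described as separate steps of
   the procedure being implemented.
5. **Membership graph.** Edge distance is d = 1 − u by default
   (−ln u available). Under 1 − u the shortest subject–subject path is
   always the best two-hop route through a single centroid (proved by the
   row-stochasticity of U: any subject detour costs ≥ 1), which the suite
   verifies against Dijkstra on 100 random instances at 1e-12. The ASWP
   permutation null draws B uniform subject subsets of the labeled size;
   *both* tails are reported because the direction convention ("compact"
   = small ASWP under 1 − u) is a package decision — the source
   description of direction is internally inconsistent, and Table-scale
   ASWP magnitudes (≈ 0.19–0.29) match two-hop 1 − u distances for strong
   memberships. p-values use (count + 1)/(B + 1) smoothing and are never 0.
6. **Longitudinal transitions.** Follow-ups are profiled by independent
   fits, aligned by Hungarian assignment on centroid Euclidean distance
   (label-pattern matching available). Complete cases only. The movement
   ratio of profile i is (row sum − diagonal)/row sum of the transition
   count matrix; the suite checks this against a subject-wise tally.
7. **PLSR.** PLS2 NIPALS with X-deflation on standardized predictors and
   centered (unscaled) membership responses — leaving Y unscaled preserves
   the simplex structure, so coefficient rows sum to ≈ 0 across profiles,
   which is asserted. Component count maximizes 10-fold cross-validated
   Q². Permutation (same Y-row permutations for all coefficients, one
   stream) gives the model p from the R² null and two-sided coefficient
   p-values; BH-FDR is applied across all predictor × profile cells of one
   model. Permuting rows of Y (rather than residuals) is the simplest
   exchangeable-null choice and is calibrated: the suite checks the null
   p-value distribution is uniform (KS, 200 replicates).
8. **Factor scores.** Split-half estimation: iterated principal-axis
   factoring (communalities from squared multiple correlations, update
   until Δ < 1e-6, Heywood cases clipped to 1 − 1e-6 with a warning),
   oblimin (quartimin, gradient-projection) rotation by default because
   cognitive factors correlate, varimax available; q = 3. The
   confirmatory step is reduced to Tucker congruence (≥ 0.9) of loadings
   independently re-estimated on the held-out half — full CFA fit indices
   are out of scope. Scores are Thurstone regression estimates
   ŝ = z R⁻¹ (ΛΦ), standardized. With 4 indicators per factor at loading
   0.7 the theoretical score–factor correlation ceiling (determinacy) is
   ≈ 0.89; recovery tests use 6 indicators per factor where the ceiling
   is ≈ 0.92.

## Synthetic study design

The generator is first-class code and defines the conditions under which
every property is tested. Defaults, chosen once to emulate the geometry
reported for large developmental cohorts:

- **4 profiles** over (VA, EFPS, MEM, int, ext, stress): MC/HSI
  (0,0,0,1.2,0.2,1.0), MC/HE (0,0,0,0.2,1.2,0.1), HC/LB
  (0.8,0.8,0.8,−0.4,−0.4,−0.4), LC/LB (−0.8,…,−0.4,…). Mixing weights
  (0.17, 0.15, 0.36, 0.32) follow the relative profile sizes of the
  reference 4-profile solution (two large low-behavior profiles, two
  smaller high-behavior ones).
- **Within-profile spread** 0.3 sd, isotropic. This puts neighboring
  centroids ≈ 5 within-sd apart — separated enough that hardened labels
  are recoverable (the regime the recovery criteria require) while
  memberships remain graded. FCM with m = 2 shows a known centroid-shrinkage
  bias that grows with overlap; at this spread the Hungarian-matched
  centroid error stays below 0.1 sd at n = 2000.
- **Covariate effects**: age slope 0.004/month and a 0.15 sd sex shift on
  every feature — small, realistic nuisance structure that
  residualization must remove.
- **Diagnoses**: Bernoulli with log-odds linear in the true membership
  vector (base rate 5%; AD loaded on MC/HSI, ADHD on MC/HE). Logistic is
  the minimal monotone link producing the observed profile-wise
  aggregation of diagnoses.
- **Environment**: 6 predictors, each a ±1 linear load on one profile's
  true membership plus unit noise.
- **Transitions**: stay-probabilities (0.45, 0.55, 0.69, 0.69) echo the
  reported movement ratios (high-behavior profiles move ≈ 15–25 points
  more); movers from high-behavior profiles land mostly in the two
  low-behavior profiles, which otherwise exchange mostly with each other.
  Under these defaults the pipeline measures ≈ 61–63% two-wave stability.
- **Missingness**: a configurable cohort × feature blanking pattern
  (default use: the stress scale absent in one validation cohort).

True memberships are computed from the planted mixture itself, so the
ground-truth record supports membership-level as well as label-level
recovery checks. What the generator does *not* emulate: item-level
questionnaire structure, non-Gaussian feature tails, informative
missingness, attrition correlated with profile, and measurement
non-invariance across cohorts. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness to
those real-data complications.

## Problem sizes

The suite and acceptance script run at desk scale, chosen as the smallest
sizes at which the sampling-error bounds in the tests are comfortably
binding: discovery cohorts of n = 1000–2000 for recovery and selection
checks, n = 400–800 for pipeline wiring, 200 replicates at B = 199 for
permutation calibration, B = 5000 for single aggregation tests, and 20
seeds for selection-frequency checks. The acceptance script's reference
run (n = 2000 discovery + 300 validation, two timepoints) completes in
well under a minute per stage.

## Numerical conventions and edge cases

- One global seed; each stage derives an independent substream keyed by a
  stage name (`numpy` SeedSequence spawning), so results are reproducible
  end-to-end and insensitive to stage order.
- Membership rows are validated to sum to 1 within 1e-9 everywhere.
- Permutation subset means fix the summation order (sorted indices), so
  identical subsets give bit-identical statistics.
- Degenerate inputs fail loudly and specifically: constant feature within
  a cohort, all-identical points, k ≥ n, fewer donors than k, non-SPD or
  tampered serialized covariances, zero-variance predictors, p-values
  outside [0, 1].
- Exact argmax ties in primary-profile assignment resolve to the lowest
  profile index and are flagged.
- Model files are versioned JSON; loading any other version is an error.

## Known limitations

- Silhouette on hardened labels (not a fuzzy silhouette variant) drives
  k selection; with heavily overlapping profiles it can under-select.
- Per-profile fuzzy covariances assume enough effective weight per
  profile; tiny profiles fall back on heavy ridge regularization.
- The ASWP test's power depends on how concentrated the labeled set is
  relative to the background mixture; moderate enrichment in a small
  profile can be undetectable at realistic sample sizes (the permutation
  p is then honestly non-significant).
- No multiple imputation, no longitudinal-aware imputation, no
  measurement-invariance testing, no possibilistic clustering, no
  automatic fuzzifier selection.
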