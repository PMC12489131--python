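# fuzzyprofiles

Fuzzy cognitive-behavioral profiling for developmental cohort studies.

Children and adolescents rarely fall into crisp diagnostic boxes: cognition
and behavior vary continuously, and a single child can resemble several
phenotypic groups at once. `fuzzyprofiles` implements a profiling framework
that embraces this: instead of assigning each subject to one cluster, it
gives every subject a *membership vector* — graded degrees of belonging to
each of k cognitive-behavioral profiles — and builds the downstream
statistics (diagnosis aggregation, longitudinal stability, environmental
associations) directly on those memberships. It is written for
epidemiologists and clinical researchers working with multi-cohort,
multi-timepoint tabular data: standardized cognitive factor scores (verbal
ability VA, executive function/processing speed EFPS, memory MEM) and
behavioral scales (internalizing, externalizing, stress).

## The model

**Profiles.** Fuzzy C-means minimizes
J(U, C) = Σᵢ Σₖ u_ik^m ‖x_k − c_i‖² by alternating the closed-form updates

u_ik = 1 / Σⱼ (d_ik/d_jk)^{2/(m−1)},  c_i = Σₖ u_ik^m x_k / Σₖ u_ik^m,

where m > 1 (default 2) is the fuzzifier controlling overlap softness and
the number of profiles k is selected by the silhouette score of the
hardened partition. After fitting, per-profile fuzzy covariance matrices
Σᵢ are estimated and the final memberships are recomputed from the
**Mahalanobis** distance d_ik = √((x_k − c_i)ᵀ Σᵢ⁻¹ (x_k − c_i)), so that
elongated or correlated profiles are represented faithfully. Because the
membership formula needs only centroids and covariances, subjects from a
*new* cohort are mapped onto existing profiles without refitting — the
core reuse mechanism for replication across studies of any size.

**Diagnosis aggregation.** Subjects and centroids form a bipartite graph
with edge distance 1 − u_ik. The average shortest weighted path (ASWP)
among subjects carrying a diagnosis is compared against the ASWP of
equally sized random subject sets (5000 permutations): diagnosed subjects
that concentrate inside particular profiles have a shorter-than-random
ASWP. Both tails are reported; p-values use (count + 1)/(B + 1) smoothing
and Benjamini–Hochberg FDR across the diagnosis family.

**Longitudinal stability.** Profiles are fitted independently per
follow-up, aligned by Hungarian matching on centroids, and each subject's
primary profile (highest membership) is tracked: the stability percentage
and the per-profile movement ratio (leavers / initial members, reported as
`0.55 (54.91%)`).

**Environmental associations.** Membership columns sum to one and are
collinear, so associations with environmental predictors use PLS2 (NIPALS)
— paired latent components maximizing predictor–membership covariance —
with the component count chosen by 10-fold cross-validated Q², model and
coefficient significance by permutation (10,000 iterations by default),
and BH-FDR over all predictor × profile coefficients.

Upstream utilities cover cross-cohort harmonization, covariate
residualization (age, sex, ethnicity, handedness), KNN imputation of a
scale missing wholesale in one cohort, and split-half exploratory factor
analysis producing the three cognitive factor scores.

## Worked example

`examples/01_fit_profiles.py` generates a synthetic discovery cohort with
four planted profiles, preprocesses it, and fits the model:

```
 k  silhouette  objective
 2       0.396   3942.877
 3       0.540   1942.134
 4       0.548   1344.893
 5       0.382   1069.686
 6       0.244    868.517
-> selected k = 4 profiles (highest mean silhouette)

profile | n (primary) | centroid (VA EFPS MEM int ext stress)
MC/HSI  |  253        | -0.05 -0.05 -0.07 +1.79 +0.41 +1.72
HC/LB   |  553        | +1.04 +1.03 +1.03 -0.55 -0.57 -0.53
LC/LB   |  462        | -1.16 -1.16 -1.16 -0.53 -0.52 -0.53
MC/HE   |  232        | -0.09 -0.06 -0.06 +0.32 +1.77 +0.33

recovery vs planted truth: centroid error 0.096 sd, label agreement 99.7%
```

The silhouette table shows why k = 4 wins; the four centroids read as two
large low-behavior profiles split by cognition (HC/LB, LC/LB) and two
smaller moderate-cognition profiles with elevated stress/internalizing
(MC/HSI) or externalizing (MC/HE) symptoms. The recovery line compares the
fit against the generator's planted truth. The other examples cover
out-of-sample prediction (`02`), the ASWP diagnosis test (`03`),
longitudinal stability (`04`), PLSR with permutation inference (`05`), and
split-half factor analysis (`06`). A thin CLI
(`fuzzyprofiles simulate|preprocess|fit-profiles|predict|graph-test|transitions|plsr`)
wraps the same calls for shell pipelines.

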