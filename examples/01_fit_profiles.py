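"""Fit fuzzy cognitive-behavioral profiles on a synthetic discovery cohort.

Generates a cohort with four planted profiles, preprocesses it
(residualization + standardization), selects the number of profiles by
silhouette, fits fuzzy C-means, and labels the centroids.
"""

import numpy as np

import fuzzyprofiles as fp

spec = fp.SyntheticSpec(n_per_cohort={"DISC": 1500}, seed=42)
tables, truth = fp.generate(spec)
table = fp.residualize(tables[0])
X = table.features
X = (X - X.mean()) / X.std(ddof=0)

k_star, sil = fp.select_k(X, range(2, 8), seed=42, n_init=3)
print("silhouette by k:")
print(sil.round(3).to_string(index=False))
print(f"-> selected k = {k_star} profiles (highest mean silhouette)\n")

model, U = fp.fit_fcm(X, k_star, seed=42)
fp.label_profiles(model)
counts = np.bincount(U.hard_labels(), minlength=model.k)
print("profile | n (primary) | centroid (VA EFPS MEM int ext stress)")
for i, lab in enumerate(model.labels):
    c = " ".join(f"{v:+.2f}" for v in model.centroids[i])
    print(f"{lab:8s}| {counts[i]:4d}        | {c}")
print("\nEach centroid is a prototype in standardized feature space;")
print("labels read cognition tier (H/M/L) / dominant behavioral elevation.")

rec = fp.truth_compare(model.centroids, U.hard_labels(), truth,
                       true_centroids=spec.standardized_centroids())
print(f"\nrecovery vs planted truth: centroid error {rec['centroid_error_mean']:.3f} sd, "
      f"label agreement {rec['label_agreement']:.1%}")
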