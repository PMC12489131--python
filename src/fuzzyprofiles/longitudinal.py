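"""Longitudinal profile stability: transitions, movement ratios, trajectories.

Profiles are fitted independently at each follow-up, so before transitions
can be counted the profile indices of the later fit must be aligned with
the earlier one. Alignment is by Hungarian assignment on the Euclidean
distance between centroid pairs (label-pattern matching is available as an
alternative through ``match_profiles``).

Each subject's *primary profile* is the one with the highest membership
value. Stability between two timepoints is the percentage of complete-case
subjects whose primary profile is unchanged; the per-profile movement
ratio divides the number of subjects leaving a profile by the number who
started in it. Reports pair the ratio with its percentage in the
``0.55 (54.91%)`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .fuzzy_profiles import MembershipMatrix, ProfileModel

__all__ = [
    "main_profile",
    "match_profiles",
    "transition_summary",
    "trajectory_paths",
    "TransitionSummary",
    "format_ratio",
]


@dataclass
class TransitionSummary:
    counts: np.ndarray              # k x k, from-profile x to-profile
    stability_percent: float
    movement_ratio: np.ndarray      # k
    n_complete: int
    profile_labels: tuple[str, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        labels = self.profile_labels or [f"profile_{i + 1}" for i in range(len(self.counts))]
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def ratio_table(self) -> pd.DataFrame:
        labels = self.profile_labels or [f"profile_{i + 1}" for i in range(len(self.counts))]
        return pd.DataFrame({
            "movement_ratio": self.movement_ratio,
            "display": [format_ratio(r) for r in self.movement_ratio],
        }, index=labels)


def format_ratio(r: float) -> str:
    """Render a movement ratio as e.g. ``0.55 (54.91%)``."""
    return f"{r:.2f} ({100 * r:.2f}%)"


def main_profile(U: MembershipMatrix) -> pd.DataFrame:
    """Primary profile per subject: row argmax, lowest index on exact ties."""
    u = U.u
    idx = u.argmax(axis=1)  # numpy argmax already takes the lowest index on ties
    tie = (u == u.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame({"profile": idx, "tie": tie}, index=U.row_ids)


def match_profiles(reference: ProfileModel, other: ProfileModel,
                   method: str = "centroids") -> np.ndarray:
    """Permutation mapping other's profile indices onto the reference's.

    ``mapping[j] = i`` means profile j of ``other`` corresponds to profile
    i of ``reference``. Default is Hungarian assignment on centroid
    Euclidean distance; ``method='labels'`` matches by identical label
    strings (requires both models labeled, labels bijective).
    """
    if method == "centroids":
        cost = cdist(other.centroids, reference.centroids)
        rows, cols = linear_sum_assignment(cost)
        mapping = np.empty(other.k, dtype=int)
        mapping[rows] = cols
        return mapping
    if method == "labels":
        if reference.labels is None or other.labels is None:
            raise ValueError("label matching requires labeled models")
        ref_idx = {lab: i for i, lab in enumerate(reference.labels)}
        try:
            return np.array([ref_idx[lab] for lab in other.labels])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} absent from reference model") from exc
    raise ValueError(f"unknown matching method {method!r}")


def _align(a1: pd.DataFrame, a2: pd.DataFrame) -> pd.Index:
    common = a1.index.intersection(a2.index)
    if len(common) == 0:
        raise ValueError("no subjects present at both timepoints")
    return common


def transition_summary(assignments_t1: pd.DataFrame, assignments_t2: pd.DataFrame,
                       k: int | None = None,
                       profile_labels: tuple[str, ...] | None = None,
                       ) -> TransitionSummary:
    """Counts matrix, stability percentage and movement ratios over complete cases.

    Inputs are the frames returned by :func:`main_profile`, indexed by
    subject id; only subjects present at both timepoints contribute.
    """
    common = _align(assignments_t1, assignments_t2)
    p1 = assignments_t1.loc[common, "profile"].to_numpy()
    p2 = assignments_t2.loc[common, "profile"].to_numpy()
    k = k or int(max(p1.max(), p2.max()) + 1)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (p1, p2), 1)
    n = len(common)
    stability = 100.0 * np.trace(counts) / n
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ratio = np.where(row_sums > 0,
                         (row_sums - np.diag(counts)) / np.maximum(row_sums, 1), np.nan)
    return TransitionSummary(counts, stability, ratio, n, profile_labels)


def trajectory_paths(assignments: list[pd.DataFrame],
                     profile_labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Count subjects per profile trajectory across all timepoints.

    Returns one row per observed (p_t1, p_t2, ..., p_tT) tuple with its
    count — the edge list of a Sankey diagram. Only subjects present at
    every timepoint are counted, so marginal flows per consecutive pair
    agree with :func:`transition_summary` on the same subject set.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two timepoints")
    common = assignments[0].index
    for a in assignments[1:]:
        common = common.intersection(a.index)
    if len(common) == 0:
        raise ValueError("no subjects present at all timepoints")
    cols = {}
    for t, a in enumerate(assignments, start=1):
        prof = a.loc[common, "profile"]
        if profile_labels is not None:
            prof = prof.map(dict(enumerate(profile_labels)))
        cols[f"t{t}"] = prof
    traj = pd.DataFrame(cols)
    out = traj.value_counts().rename("count").reset_index()
    return out.sort_values(list(out.columns[:-1])).reset_index(drop=True)
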