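"""Subject-centroid membership graph and the ASWP permutation test.

Subjects and profile centroids form a bipartite weighted graph: each
subject is connected to every centroid with its membership value as the
edge weight. For path computations the weight is turned into a distance,
either d = 1 - u (default) or d = -ln u. Under d = 1 - u, two subjects
with strong membership in the same profile are a short two-hop path apart,
so a set of subjects that aggregates inside one profile has a *small*
average shortest weighted path (ASWP).

Whether a diagnosis aggregates non-randomly is tested by permutation:
the observed ASWP of the diagnosed subjects is compared with the ASWP of
B equally sized uniform random subject subsets. Both tails are reported;
under the default transform the left tail (smaller-than-random ASWP) is
the "compact aggregation" direction. The p-values use the add-one
smoothing (count + 1)/(B + 1), so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .fuzzy_profiles import MembershipMatrix
from .io_config import logger, substream

__all__ = [
    "build_graph",
    "aswp",
    "subject_distance_matrix",
    "aswp_permutation_test",
    "psypatho_index",
    "diagnosis_profile_distribution",
    "ASWPResult",
]


@dataclass
class ASWPResult:
    observed: float
    null: np.ndarray
    p_left: float
    p_right: float
    B: int
    seed: int
    label: str
    n_labeled: int


def _distances(u: np.ndarray, transform: str) -> np.ndarray:
    if transform == "one_minus_u":
        return 1.0 - u
    if transform == "neg_log_u":
        with np.errstate(divide="ignore"):
            return -np.log(u)
    raise ValueError(f"unknown distance transform {transform!r}")


def build_graph(U: MembershipMatrix, transform: str = "one_minus_u") -> nx.Graph:
    """Bipartite subject-centroid graph with weight u and distance d(u).

    Edges with u = 0 are dropped under ``neg_log_u`` (infinite distance)
    and kept with d = 1 under ``one_minus_u``.
    """
    if U.n == 0:
        raise ValueError("empty membership matrix")
    d = _distances(U.u, transform)
    g = nx.Graph(transform=transform)
    subject_nodes = [("s", sid) for sid in U.row_ids]
    centroid_nodes = [("c", i) for i in range(U.k)]
    g.add_nodes_from(subject_nodes, bipartite=0)
    g.add_nodes_from(centroid_nodes, bipartite=1)
    for a, s_node in enumerate(subject_nodes):
        for i, c_node in enumerate(centroid_nodes):
            if U.u[a, i] == 0 and transform == "neg_log_u":
                continue
            g.add_edge(s_node, c_node, weight=float(U.u[a, i]), distance=float(d[a, i]))
    return g


def aswp(graph: nx.Graph, subject_set: list) -> float:
    """Mean shortest-path distance over all unordered pairs of subjects.

    Paths may traverse any centroid (and other subjects).
    """
    nodes = [("s", s) for s in subject_set]
    if len(set(nodes)) < len(nodes):
        raise ValueError("subject_set contains duplicates")
    if len(nodes) < 2:
        raise ValueError("need at least 2 subjects")
    for node in nodes:
        if node not in graph:
            raise KeyError(f"unknown subject id {node[1]!r}")
    total = 0.0
    count = 0
    for i, src in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(graph, src, weight="distance")
        for dst in nodes[i + 1:]:
            total += lengths[dst]
            count += 1
    return total / count


def subject_distance_matrix(graph: nx.Graph) -> tuple[np.ndarray, list]:
    """All-pairs subject-subject shortest distances (for fast permutation)."""
    subjects = [n for n in graph.nodes if n[0] == "s"]
    n = len(subjects)
    idx = {node: i for i, node in enumerate(subjects)}
    D = np.zeros((n, n))
    for node in subjects:
        lengths = nx.single_source_dijkstra_path_length(graph, node, weight="distance")
        i = idx[node]
        for other, d in lengths.items():
            if other[0] == "s":
                D[i, idx[other]] = d
    return D, [s for _, s in subjects]


def _mean_offdiag(D: np.ndarray, rows: np.ndarray) -> float:
    rows = np.sort(rows)  # fixed summation order: same subset -> identical float
    sub = D[np.ix_(rows, rows)]
    L = len(rows)
    return float(sub.sum() / (L * (L - 1)))  # symmetric, zero diagonal


def aswp_permutation_test(graph: nx.Graph, labels, B: int = 5000,
                          seed: int = 0, label_name: str = "diagnosis",
                          ) -> ASWPResult:
    """Permutation null for the ASWP of the labeled subject set.

    ``labels`` is a binary flag per subject (aligned with the graph's
    subject ids via a pandas Series, or positional otherwise). The null
    draws B uniform random subject subsets of the same size.
    """
    D, subject_ids = subject_distance_matrix(graph)
    n = len(subject_ids)
    if isinstance(labels, pd.Series):
        flags = labels.reindex(subject_ids).to_numpy(dtype=float)
    else:
        flags = np.asarray(labels, dtype=float)
        if len(flags) != n:
            raise ValueError(f"labels length {len(flags)} != number of subjects {n}")
    labeled = np.flatnonzero(flags == 1)
    L = len(labeled)
    if L < 2:
        raise ValueError("need at least 2 labeled subjects")
    if L > n:
        raise ValueError("labeled count exceeds number of subjects")
    observed = _mean_offdiag(D, labeled)
    rng = substream(seed, f"aswp:{label_name}")
    null = np.empty(B)
    for b in range(B):
        rows = rng.choice(n, size=L, replace=False)
        null[b] = _mean_offdiag(D, rows)
    p_left = (np.sum(null <= observed) + 1) / (B + 1)
    p_right = (np.sum(null >= observed) + 1) / (B + 1)
    return ASWPResult(observed, null, float(p_left), float(p_right), B, seed,
                      label_name, L)


def psypatho_index(diagnoses: pd.DataFrame) -> pd.Series:
    """1 iff any available diagnosis flag is 1; all-missing stays missing."""
    if diagnoses.shape[1] < 1:
        raise ValueError("need at least one diagnosis column")
    any_one = (diagnoses == 1).any(axis=1)
    all_missing = diagnoses.isna().all(axis=1)
    out = any_one.astype(float)
    out[all_missing] = np.nan
    return out


def diagnosis_profile_distribution(U: MembershipMatrix,
                                   diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Percentage of flagged subjects per primary profile, one row per diagnosis.

    Rows sum to 100%. A diagnosis with zero flagged subjects is emitted as
    an all-NaN row with a warning.
    """
    hard = U.hard_labels()
    cols = U.profile_labels or [f"profile_{i + 1}" for i in range(U.k)]
    rows = {}
    dx = diagnoses.reset_index(drop=True)
    for name in dx.columns:
        flagged = np.flatnonzero(dx[name].to_numpy() == 1)
        if len(flagged) == 0:
            logger.warning("diagnosis %r has zero cases", name)
            rows[name] = np.full(U.k, np.nan)
            continue
        counts = np.bincount(hard[flagged], minlength=U.k)
        rows[name] = 100.0 * counts / counts.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(cols))
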