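"""Fuzzy C-means profiles with Mahalanobis membership functions.

The profiling model has two stages. Fitting runs classical (Euclidean)
fuzzy C-means by alternating optimization of

    J(U, C) = sum_i sum_k u_ik^m ||x_k - c_i||^2,

with the standard closed-form updates for memberships and centroids. After
the centroids converge, per-profile fuzzy covariance matrices are estimated
and the final membership of every subject is recomputed from the
*Mahalanobis* distance to each centroid,

    d_ik = sqrt((x_k - c_i)^T Sigma_i^{-1} (x_k - c_i)),
    u_ik = 1 / sum_j (d_ik / d_jk)^{2/(m-1)},

so that elongated or correlated profiles are not penalized by spherical
geometry. The same formula, applied to stored centroids and covariances,
predicts memberships for subjects from a new cohort without refitting —
the mechanism that lets profiles discovered in one study be mapped onto
another.

The fuzzifier m (> 1) controls overlap softness: as m -> 1 memberships
approach hard assignment, larger m blurs profile boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .io_config import (
    BEHAVIORAL_FEATURES,
    COGNITIVE_FEATURES,
    DEFAULT_FEATURES,
    logger,
    substream,
)

__all__ = [
    "ProfileModel",
    "MembershipMatrix",
    "fit_fcm",
    "fuzzy_covariance",
    "compute_memberships",
    "predict_memberships",
    "select_k",
    "label_profiles",
]


@dataclass
class ProfileModel:
    """k profile centroids plus per-profile covariances and the fuzzifier."""

    centroids: np.ndarray                  # k x p
    covariances: list[np.ndarray]          # k matrices, p x p, SPD
    fuzzifier: float
    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    labels: tuple[str, ...] | None = None
    objective: float = np.nan
    seed: int | None = None
    n_iter: int = 0
    tol: float = 0.0

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids contain non-finite values")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if len(self.covariances) != self.k:
            raise ValueError("one covariance matrix required per profile")
        for i, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance {i} is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance {i} is not positive definite")
        if self.labels is not None and len(set(self.labels)) != self.k:
            raise ValueError("profile labels must be unique, one per profile")


@dataclass
class MembershipMatrix:
    """n x k degrees of belonging; each row sums to 1."""

    u: np.ndarray
    row_ids: pd.Index | None = None
    profile_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2:
            raise ValueError("membership matrix must be 2-d")
        if np.any(self.u < -1e-12) or np.any(self.u > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        sums = self.u.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("membership rows must sum to 1 (tolerance 1e-9)")
        if self.row_ids is None:
            self.row_ids = pd.RangeIndex(len(self.u))
        else:
            self.row_ids = pd.Index(self.row_ids)

    @property
    def n(self) -> int:
        return self.u.shape[0]

    @property
    def k(self) -> int:
        return self.u.shape[1]

    def hard_labels(self) -> np.ndarray:
        return self.u.argmax(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = self.profile_labels or [f"profile_{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.u, index=self.row_ids, columns=list(cols))


def _membership_from_distances(d: np.ndarray, m: float) -> np.ndarray:
    """u_ik = 1 / sum_j (d_ik/d_jk)^{2/(m-1)} with the zero-distance rule.

    A zero distance makes the row the indicator of that profile; exact ties
    among several zero distances split the mass equally.
    """
    d = np.asarray(d, dtype=float)
    n, k = d.shape
    zero = d <= 0.0
    u = np.zeros_like(d)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    reg = ~any_zero
    if reg.any():
        power = 2.0 / (m - 1.0)
        inv = d[reg] ** (-power)
        u[reg] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _fcm_single(X: np.ndarray, k: int, m: float, tol: float, max_iter: int,
                rng: np.random.Generator,
                ) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = X.shape[0]
    # init memberships from a Dirichlet draw: strictly positive rows summing to 1
    u = rng.dirichlet(np.ones(k), size=n)
    prev_j = np.inf
    history: list[float] = []
    for it in range(1, max_iter + 1):
        um = u ** m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = cdist(X, centroids, metric="sqeuclidean")
        j = float((um * d2).sum())
        if j > prev_j + 1e-9 * max(1.0, abs(prev_j)):
            raise AssertionError(f"FCM objective increased at iteration {it}")
        history.append(j)
        u_new = _membership_from_distances(np.sqrt(np.maximum(d2, 0.0)), m)
        delta = np.abs(u_new - u).max()
        u = u_new
        prev_j = j
        if delta < tol:
            break
    um = u ** m
    centroids = (um.T @ X) / um.sum(axis=0)[:, None]
    d2 = cdist(X, centroids, metric="sqeuclidean")
    j = float((u ** m * d2).sum())
    return centroids, u, j, it, history


def fit_fcm(X, k: int, m: float = 2.0, tol: float = 1e-6, max_iter: int = 1000,
            seed: int = 0, n_init: int = 10,
            feature_names: Sequence[str] | None = None,
            row_ids=None) -> tuple[ProfileModel, MembershipMatrix]:
    """Fit fuzzy C-means; keep the best of ``n_init`` seeded restarts by J.

    Returns the model with Mahalanobis-ready fuzzy covariances and the
    *Mahalanobis-recomputed* membership matrix.
    """
    Xarr = _as_matrix(X)
    n, p = Xarr.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of subjects ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if np.ptp(Xarr, axis=0).max() == 0:
        raise ValueError("all points identical: degenerate input")

    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or tuple(X.columns)
        row_ids = X.index if row_ids is None else row_ids
    feature_names = tuple(feature_names) if feature_names else tuple(
        f"f{i}" for i in range(p))

    rng = substream(seed, f"fcm:k={k}")
    best = None
    for _ in range(n_init):
        centroids, u, j, n_it, history = _fcm_single(Xarr, k, m, tol, max_iter, rng)
        if best is None or j < best[2]:
            best = (centroids, u, j, n_it, history)
    centroids, u_eucl, j, n_it, history = best

    covs = fuzzy_covariance(Xarr, u_eucl, centroids, m)
    model = ProfileModel(
        centroids=centroids, covariances=covs, fuzzifier=m,
        feature_names=feature_names, objective=j, seed=seed,
        n_iter=n_it, tol=tol,
    )
    model.objective_history = history  # per-iteration J of the winning restart
    memberships = compute_memberships(Xarr, model, row_ids=row_ids)
    return model, memberships


def fuzzy_covariance(X, U, centroids, m: float = 2.0,
                     eps_scale: float = 1e-6) -> list[np.ndarray]:
    """Membership-weighted covariance per profile, ridge-regularized to SPD.

    Sigma_i = sum_k u_ik^m (x_k - c_i)(x_k - c_i)^T / sum_k u_ik^m + eps I,
    eps = eps_scale * trace(Sigma_i) / p.
    """
    X = _as_matrix(X)
    U = np.asarray(U, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    k, p = centroids.shape
    covs = []
    for i in range(k):
        w = U[:, i] ** m
        total = w.sum()
        if total < 1e-12:
            raise ValueError(f"profile {i} has vanishing total membership weight")
        diff = X - centroids[i]
        cov = (w[:, None] * diff).T @ diff / total
        eps = eps_scale * max(np.trace(cov), 1e-12) / p
        cov = cov + eps * np.eye(p)
        covs.append((cov + cov.T) / 2.0)
    return covs


def mahalanobis_distances(X, model: ProfileModel) -> np.ndarray:
    """n x k matrix of Mahalanobis distances to each profile centroid."""
    X = _as_matrix(X)
    n = X.shape[0]
    d = np.empty((n, model.k))
    for i in range(model.k):
        diff = X - model.centroids[i]
        L = np.linalg.cholesky(model.covariances[i])
        z = solve_triangular(L, diff.T, lower=True)
        d[:, i] = np.sqrt((z ** 2).sum(axis=0))
    return d


def compute_memberships(X, model: ProfileModel, row_ids=None) -> MembershipMatrix:
    """Memberships from Mahalanobis distance to each profile centroid."""
    Xarr = _as_matrix(X)
    bad = ~np.isfinite(Xarr).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite feature values in rows {np.flatnonzero(bad)[:5].tolist()}")
    if isinstance(X, pd.DataFrame) and row_ids is None:
        row_ids = X.index
    d = mahalanobis_distances(Xarr, model)
    u = _membership_from_distances(d, model.fuzzifier)
    return MembershipMatrix(u, row_ids=row_ids, profile_labels=model.labels)


def predict_memberships(X_new, model: ProfileModel, row_ids=None) -> MembershipMatrix:
    """Map new subjects onto stored profiles — no refit, works for n = 1.

    If ``X_new`` is a DataFrame its columns must match the model's feature
    names (order included).
    """
    if isinstance(X_new, pd.DataFrame):
        cols = tuple(X_new.columns)
        if cols != tuple(model.feature_names):
            missing = set(model.feature_names) - set(cols)
            extra = set(cols) - set(model.feature_names)
            raise ValueError(
                "feature names do not match the model: "
                f"missing={sorted(missing)} extra={sorted(extra)} order={list(cols)}"
            )
    else:
        arr = _as_matrix(X_new)
        if arr.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {arr.shape[1]}"
            )
    return compute_memberships(X_new, model, row_ids=row_ids)


def select_k(X, k_range: Sequence[int] = range(2, 11), m: float = 2.0,
             seed: int = 0, n_init: int = 4, tol: float = 1e-5,
             max_iter: int = 300) -> tuple[int, pd.DataFrame]:
    """Choose the number of profiles by mean silhouette of hardened labels.

    For each candidate k the FCM fit is hardened by row-argmax and scored
    with the Euclidean silhouette; k* is the argmax. A k whose hardened
    partition leaves a profile empty is scored -inf with a warning.
    """
    Xarr = _as_matrix(X)
    rows = []
    for k in k_range:
        if not (2 <= k <= Xarr.shape[0] - 1):
            raise ValueError(f"candidate k={k} outside [2, n-1]")
        model, memberships = fit_fcm(Xarr, k, m=m, tol=tol, max_iter=max_iter,
                                     seed=seed, n_init=n_init)
        hard = memberships.hard_labels()
        if len(np.unique(hard)) < k:
            logger.warning("k=%d produced an empty hardened profile; scored -inf", k)
            score = -np.inf
        else:
            score = float(silhouette_score(Xarr, hard, metric="euclidean"))
        rows.append({"k": k, "silhouette": score, "objective": model.objective})
    table = pd.DataFrame(rows)
    k_star = int(table.loc[table["silhouette"].idxmax(), "k"])
    return k_star, table


def label_profiles(model: ProfileModel, score_threshold: float = 0.5,
                   feature_names: Sequence[str] | None = None) -> ProfileModel:
    """Attach deterministic descriptive labels to centroids.

    The cognitive tier {L, M, H} comes from the mean of the three cognitive
    factor coordinates against +/- ``score_threshold``; the behavioral tag
    names the behavioral dimensions whose coordinate exceeds +threshold
    (internalizing -> I, externalizing -> E, stress -> S), or LB when none
    does. Example labels: HC/LB, LC/LB, MC/HE, MC/HSI.
    """
    names = tuple(feature_names) if feature_names else model.feature_names
    idx = {n: i for i, n in enumerate(names)}
    for needed in (*COGNITIVE_FEATURES, *BEHAVIORAL_FEATURES):
        if needed not in idx:
            raise ValueError(f"feature {needed!r} required for labeling")
    tag_letter = {"internalizing": "I", "externalizing": "E", "stress": "S"}
    # order tags stress-before-internalizing so stress+internalizing reads "HSI"
    tag_order = ("stress", "internalizing", "externalizing")

    labels = []
    for c in model.centroids:
        cog = np.mean([c[idx[f]] for f in COGNITIVE_FEATURES])
        tier = "H" if cog > score_threshold else ("L" if cog < -score_threshold else "M")
        high = [f for f in tag_order if c[idx[f]] > score_threshold]
        if not high:
            tag = "LB"
        else:
            # externalizing alone reads HE; stress/internalizing combos read HS/HI/HSI
            tag = "H" + "".join(tag_letter[f] for f in high)
        labels.append(f"{tier}C/{tag}")
    # disambiguate duplicates with the centroid index
    seen: dict[str, int] = {}
    final = []
    for i, lab in enumerate(labels):
        if labels.count(lab) > 1:
            lab = f"{lab}#{i + 1}"
        final.append(lab)
    model.labels = tuple(final)
    return model
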