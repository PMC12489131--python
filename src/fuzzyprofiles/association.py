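"""Environment-to-membership association via PLSR with permutation inference.

Membership values of the k profiles are mutually collinear (rows sum to 1),
so ordinary least squares per profile is ill-posed as a joint model.
Partial least squares regression (PLS2) instead extracts paired latent
components that maximize the covariance between the environmental
predictor block X and the membership block Y, and returns a coefficient
for each predictor on each profile: the sign gives the direction of the
association, the magnitude its relative importance.

The fit is the classical NIPALS algorithm with X-deflation. The number of
components is chosen by 10-fold cross-validated predictive R-squared (Q2).
Significance of the model R-squared and of every coefficient is assessed
by permuting the rows of Y jointly (one null stream shared by all
coefficients), with add-one smoothing, and the coefficient p-values are
corrected with Benjamini-Hochberg FDR over all predictor-by-profile cells.

Profile contrasts on a single score use one-way ANOVA with Tukey HSD
post-hoc comparisons, subjects grouped by primary profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_config import logger, substream

__all__ = [
    "PLSRModel",
    "PermutationReport",
    "plsr_fit",
    "plsr_select_components",
    "plsr_permutation",
    "fdr_bh",
    "anova_tukey",
]


@dataclass
class PLSRModel:
    n_components: int
    x_weights: np.ndarray       # p x A  (W)
    x_loadings: np.ndarray      # p x A  (P)
    y_loadings: np.ndarray      # k x A  (Q)
    x_scores: np.ndarray        # n x A  (T)
    y_scores: np.ndarray        # n x A
    coef: np.ndarray            # p x k, standardized-X scale
    r2: float
    x_mean: np.ndarray = field(default=None)
    x_scale: np.ndarray = field(default=None)
    y_mean: np.ndarray = field(default=None)
    predictor_names: tuple[str, ...] | None = None
    response_names: tuple[str, ...] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xs @ self.coef + self.y_mean


@dataclass
class PermutationReport:
    model_p: float
    coef_p: np.ndarray          # p x k
    coef_p_fdr: np.ndarray      # p x k
    r2_null: np.ndarray
    B: int
    seed: int


def _prep(X, Y):
    Xnames = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
    Ynames = tuple(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return X, Y, Xnames, Ynames


def _nipals(Xc: np.ndarray, Yc: np.ndarray, A: int, tol: float = 1e-12,
            max_iter: int = 1000):
    """NIPALS with X-deflation; returns W, P, Q, T, U."""
    n, p = Xc.shape
    k = Yc.shape[1]
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((k, A))
    T = np.zeros((n, A))
    Uy = np.zeros((n, A))
    X = Xc.copy()
    Y = Yc.copy()
    for a in range(A):
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm < 1e-14:
                raise ValueError(f"degenerate weight vector at component {a + 1}")
            w /= norm
            t = X @ w
            q = Y.T @ t / (t @ t)
            if np.linalg.norm(q) < 1e-14:
                break
            u = Y @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        p_a = X.T @ t / (t @ t)
        W[:, a], P[:, a], Q[:, a], T[:, a], Uy[:, a] = w, p_a, q, t, u
        X = X - np.outer(t, p_a)
        Y = Y - np.outer(t, q)
    return W, P, Q, T, Uy


def plsr_fit(X, Y, A: int, scale_y: bool = False) -> PLSRModel:
    """Fit PLS2 with A components on standardized predictors.

    Y (membership values) is centered but, by default, not scaled, which
    preserves the row-sum structure: because membership rows sum to one,
    the coefficient rows sum to ~0 across profiles.
    """
    X, Y, Xnames, Ynames = _prep(X, Y)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    if np.any(x_scale == 0):
        bad = (Xnames[int(np.flatnonzero(x_scale == 0)[0])] if Xnames
               else int(np.flatnonzero(x_scale == 0)[0]))
        raise ValueError(f"zero-variance predictor: {bad!r}")
    Xs = (X - x_mean) / x_scale
    rank = np.linalg.matrix_rank(Xs)
    if A > rank:
        raise ValueError(f"A={A} exceeds rank(X)={rank}")
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    if scale_y:
        Yc = Yc / Yc.std(axis=0, ddof=0)
    W, P, Q, T, Uy = _nipals(Xs, Yc, A)
    # B maps standardized X to centered Y: B = W (P^T W)^{-1} Q^T
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    resid = Yc - Xs @ coef
    ss_tot = (Yc ** 2).sum()
    r2 = float(1.0 - (resid ** 2).sum() / ss_tot)
    return PLSRModel(A, W, P, Q, T, Uy, coef, r2, x_mean, x_scale, y_mean,
                     Xnames, Ynames)


def plsr_select_components(X, Y, folds: int = 10, A_max: int = 5,
                           seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Pick A* maximizing 10-fold cross-validated Q2.

    Q2(A) = 1 - PRESS(A) / SS, with PRESS accumulated over seeded,
    disjoint folds and SS the squared deviation of held-out Y from the
    training mean.
    """
    X, Y, *_ = _prep(X, Y)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"n={n} smaller than the number of folds ({folds})")
    rng = substream(seed, "plsr_cv")
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    A_max = min(A_max, np.linalg.matrix_rank(X - X.mean(axis=0)))
    press = np.zeros(A_max)
    ss = 0.0
    for f in range(folds):
        test = fold_of == f
        train = ~test
        ss += ((Y[test] - Y[train].mean(axis=0)) ** 2).sum()
        for a in range(1, A_max + 1):
            model = plsr_fit(X[train], Y[train], a)
            press[a - 1] += ((Y[test] - model.predict(X[test])) ** 2).sum()
    q2 = 1.0 - press / ss
    table = pd.DataFrame({"A": np.arange(1, A_max + 1), "Q2": q2})
    a_star = int(table.loc[table["Q2"].idxmax(), "A"])
    return a_star, table


def plsr_permutation(X, Y, A: int, B: int = 10000, seed: int = 0,
                     alpha: float = 0.05) -> PermutationReport:
    """Permutation significance for the model R2 and every coefficient.

    Rows of Y are permuted jointly B times; the model p-value is the
    add-one right tail of the null R2, coefficient p-values the two-sided
    tail of |B_null| against |B_obs|. BH-FDR is applied across all
    predictor-by-profile coefficients.
    """
    if B < 100:
        logger.warning("B=%d is small; permutation p-values will be unstable", B)
    X, Y, *_ = _prep(X, Y)
    obs = plsr_fit(X, Y, A)
    rng = substream(seed, "plsr_perm")
    r2_null = np.empty(B)
    coef_exceed = np.zeros_like(obs.coef)
    abs_obs = np.abs(obs.coef)
    for b in range(B):
        perm = rng.permutation(Y.shape[0])
        null = plsr_fit(X, Y[perm], A)
        r2_null[b] = null.r2
        coef_exceed += np.abs(null.coef) >= abs_obs
    model_p = float((np.sum(r2_null >= obs.r2) + 1) / (B + 1))
    coef_p = (coef_exceed + 1) / (B + 1)
    flat_fdr = fdr_bh(coef_p.ravel(), alpha=alpha)[0]
    return PermutationReport(model_p, coef_p, flat_fdr.reshape(coef_p.shape),
                             r2_null, B, seed)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def anova_tukey(values, groups, alpha: float = 0.05,
                ) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F/p plus the Tukey HSD pairwise table.

    Groups with fewer than 2 members are excluded with a warning.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep_levels = [g for g, c in zip(*np.unique(groups, return_counts=True)) if c >= 2]
    dropped = set(np.unique(groups)) - set(keep_levels)
    if dropped:
        logger.warning("excluding groups with < 2 members: %s", sorted(map(str, dropped)))
    mask = np.isin(groups, keep_levels)
    values, groups = values[mask], groups[mask]
    if len(keep_levels) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    samples = [values[groups == g] for g in keep_levels]
    F, p = stats.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    table = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return float(F), float(p), table
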