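"""Split-half exploratory factor analysis for the cognitive factor scores.

Three latent cognitive factors — verbal ability (VA), executive
function/processing speed (EFPS), and memory (MEM) — are extracted from
raw cognitive subtest scores. The sample is split into balanced halves;
factors are estimated on the first half by iterated principal-axis
factoring and rotated (oblimin by default, since cognitive factors
correlate), and the structure is confirmed on the second half by Tucker
congruence of independently re-estimated loadings. Subject-level factor
scores use the Thurstone regression estimator

    s_hat = z R^{-1} (Lambda Phi),

where z is the standardized subtest row, R the subtest correlation matrix,
Lambda the pattern matrix and Phi the factor correlation matrix.

Principal-axis factoring iterates communalities on the reduced correlation
matrix: starting from squared multiple correlations, eigendecompose R with
communalities on the diagonal, keep the top-q components scaled by the
square roots of their eigenvalues, and update communalities from the row
sums of squared loadings until the largest change falls below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import CohortTable, logger, substream

__all__ = ["FactorModel", "split_half", "efa_fit", "factor_scores", "tucker_congruence"]


@dataclass
class FactorModel:
    loadings: np.ndarray            # p x q pattern matrix
    uniquenesses: np.ndarray        # p
    phi: np.ndarray                 # q x q factor correlations (I for orthogonal)
    rotation: str
    factor_names: tuple[str, ...]
    subtest_names: tuple[str, ...]
    corr: np.ndarray                # p x p subtest correlation matrix (fit half)
    split_seed: int | None = None

    @property
    def q(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> np.ndarray:
        # diag(Lambda Phi Lambda^T) on the correlation scale
        return np.einsum("ij,jk,ik->i", self.loadings, self.phi, self.loadings)


def split_half(table: CohortTable, stratify_by: str | None = None,
               seed: int = 0) -> tuple[CohortTable, CohortTable]:
    """Random disjoint halves, balanced overall and within each stratum.

    Half sizes differ by at most one in every stratum; a stratum of size 1
    goes deterministically to the first half, with a warning.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = substream(seed, "split_half")
    data = table.data
    first = np.zeros(n, dtype=bool)
    if stratify_by is None:
        strata = {None: np.arange(n)}
    else:
        strata = {key: idx.to_numpy() for key, idx in
                  data.reset_index(drop=True).groupby(stratify_by).groups.items()}
    for key, idx in sorted(strata.items(), key=lambda kv: str(kv[0])):
        if len(idx) == 1:
            logger.warning("stratum %r has a single row; assigned to first half", key)
            first[idx] = True
            continue
        perm = rng.permutation(idx)
        half = (len(idx) + 1) // 2
        first[perm[:half]] = True
    a = table.subset(pd.Series(first, index=data.index))
    b = table.subset(pd.Series(~first, index=data.index))
    return a, b


def _varimax(L: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    p, q = L.shape
    R = np.eye(q)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / p))
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return L @ R


def _quartimin_grad(L: np.ndarray) -> tuple[float, np.ndarray]:
    q = L.shape[1]
    L2 = L ** 2
    N = np.ones((q, q)) - np.eye(q)
    f = np.sum(L2 * (L2 @ N)) / 4.0
    return f, L * (L2 @ N)


def _oblimin(A: np.ndarray, max_iter: int = 500, tol: float = 1e-8,
             ) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-projection oblique rotation for the quartimin criterion."""
    q = A.shape[1]
    T = np.eye(q)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_grad(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X ** 2).sum(axis=0))
            Ti = np.linalg.inv(X)
            L = A @ Ti.T
            ft, Gq = _quartimin_grad(L)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        T = X
        f = ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi


def efa_fit(half: CohortTable | pd.DataFrame, subtest_names: list[str],
            q: int = 3, rotation: str = "oblimin", seed: int = 0,
            max_iter: int = 1000, tol: float = 1e-6) -> FactorModel:
    """Iterated principal-axis factoring on one half, then rotation.

    Factor order is fixed by descending explained variance, and each
    factor's sign is flipped so its largest-magnitude loading is positive.
    Heywood cases (communality > 1) are clipped with a warning.
    """
    data = half.data if isinstance(half, CohortTable) else half
    X = data[list(subtest_names)].to_numpy(dtype=float)
    p = X.shape[1]
    if q < 1:
        raise ValueError("q must be >= 1")
    if q >= p:
        raise ValueError(f"q ({q}) must be smaller than the number of subtests ({p})")
    R = pd.DataFrame(X).corr().to_numpy()  # pairwise-complete
    eig_min = np.linalg.eigvalsh(R).min()
    if eig_min <= 0:
        raise ValueError(f"subtest correlation matrix not positive definite (min eig {eig_min:.3g})")

    # start from squared multiple correlations
    h = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    L = None
    for it in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1][:q]
        lam = np.sqrt(np.maximum(vals[order], 0.0))
        L = vecs[:, order] * lam
        h_new = (L ** 2).sum(axis=1)
        if np.any(h_new > 1.0):
            logger.warning("Heywood case: clipping %d communalities to 1 - 1e-6",
                           int((h_new > 1).sum()))
            h_new = np.minimum(h_new, 1.0 - 1e-6)
        delta = np.abs(h_new - h).max()
        h = h_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"principal-axis factoring did not converge (last delta {delta:.3g})")

    if rotation == "varimax":
        L = _varimax(L)
        Phi = np.eye(q)
    elif rotation == "oblimin":
        L, Phi = _oblimin(L)
    elif rotation in (None, "none"):
        Phi = np.eye(q)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    # order by explained variance, sign so largest |loading| per factor is positive
    ssq = (L ** 2).sum(axis=0)
    order = np.argsort(ssq)[::-1]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    for j in range(q):
        i = np.abs(L[:, j]).argmax()
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
            Phi[j, :] *= -1
            Phi[:, j] *= -1

    names = tuple(f"F{j + 1}" for j in range(q))
    return FactorModel(L, 1.0 - h, Phi, rotation or "none", names,
                       tuple(subtest_names), R, split_seed=seed)


def factor_scores(model: FactorModel, table: CohortTable | pd.DataFrame,
                  score_names: list[str] | None = None) -> pd.DataFrame:
    """Thurstone regression scores, standardized, appended as q columns."""
    data = table.data if isinstance(table, CohortTable) else table
    X = data[list(model.subtest_names)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [model.subtest_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant subtest(s) cannot be standardized: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = model.corr
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(R) / R.shape[0]
        logger.warning("singular subtest correlation matrix; ridge-stabilized inverse")
        Rinv = np.linalg.inv(R + eps * np.eye(R.shape[0]))
    structure = model.loadings @ model.phi
    S = Z @ Rinv @ structure
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=0)
    names = score_names or list(model.factor_names)
    return pd.DataFrame(S, index=data.index, columns=names)


def tucker_congruence(L1: np.ndarray, L2: np.ndarray) -> np.ndarray:
    """Tucker congruence of matched factor columns (after sign alignment)."""
    num = (L1 * L2).sum(axis=0)
    den = np.sqrt((L1 ** 2).sum(axis=0) * (L2 ** 2).sum(axis=0))
    return np.abs(num / den)
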