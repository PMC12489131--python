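"""Harmonization, covariate residualization and KNN imputation.

The analysis matrix fed to the clustering stage is built in three steps,
in this order: (1) harmonize each cohort so location/scale differences
between studies are removed, (2) residualize every feature on the
covariates (age, sex, ethnicity, handedness) and re-standardize, and
(3) impute any feature missing wholesale in one cohort (the stress scale)
with a K-nearest-neighbor model over the remaining standardized features.

Harmonization here is per-cohort z-scoring: within each cohort and
feature, values are affinely rescaled to mean 0 / sd 1, which matches the
post-harmonization summary convention (cohort means ~ 0, sds ~ 1). An
empirical-Bayes batch-adjustment backend could be slotted behind the same
interface without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr

from .io_config import CohortTable, logger

__all__ = ["harmonize", "residualize", "knn_impute", "FeatureMatrix", "build_feature_matrix"]


class DegenerateScaleError(ValueError):
    """A feature is constant within a cohort; no affine rescaling exists."""


@dataclass
class FeatureMatrix:
    """n x 6 residualized, standardized analysis matrix."""

    values: pd.DataFrame          # rows indexed by subject key
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix must be complete (no missing entries)")

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def harmonize(tables: list[CohortTable], reference: str | None = None,
              ) -> tuple[list[CohortTable], pd.DataFrame]:
    """Rescale each cohort's features to mean 0 / sd 1.

    Returns the harmonized tables plus a report of the affine parameters
    (per cohort and feature) that were removed. ``reference`` names the
    cohort anchoring the convention; with per-cohort z-scoring every cohort
    ends on the reference scale, so the parameter report is what
    distinguishes it.
    """
    out = []
    params = []
    for table in tables:
        t = table.copy()
        feats = list(t.schema.features)
        for cohort, idx in t.data.groupby(t.schema.cohort).groups.items():
            for f in feats:
                col = t.data.loc[idx, f]
                vals = col.dropna()
                if len(vals) == 0:
                    # variable absent in this cohort; left for imputation
                    logger.warning("cohort %r: feature %r entirely missing; skipped",
                                   cohort, f)
                    continue
                if len(vals) < 2:
                    raise ValueError(
                        f"cohort {cohort!r}, feature {f!r}: need >= 2 non-missing values")
                mu, sd = float(vals.mean()), float(vals.std(ddof=0))
                if sd == 0:
                    raise DegenerateScaleError(
                        f"feature {f!r} is constant within cohort {cohort!r}")
                t.data.loc[idx, f] = (col - mu) / sd
                params.append({"cohort": cohort, "feature": f, "mean": mu, "sd": sd,
                               "reference": cohort == reference})
        out.append(t)
    return out, pd.DataFrame(params)


def _expand_covariates(data: pd.DataFrame, covariate_names: list[str]) -> np.ndarray:
    """Design matrix: intercept + numeric covariates + treatment-coded categoricals.

    The most frequent level of each categorical is the reference. Redundant
    (collinear) columns are dropped with a logged warning.
    """
    cols = [np.ones(len(data))]
    for name in covariate_names:
        col = data[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique(dropna=True) > 2:
            filled = col.astype(float).fillna(col.astype(float).mean())
            cols.append(filled.to_numpy())
        else:
            levels = col.value_counts(dropna=True)
            ref = levels.index[0] if len(levels) else None
            for level in levels.index[1:]:
                cols.append((col == level).to_numpy(dtype=float))
            _ = ref
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("covariate design rank-deficient (%d < %d); dropping redundant columns",
                       rank, design.shape[1])
        _, _, piv = scipy_qr(design, mode="economic", pivoting=True)
        design = design[:, np.sort(piv[:rank])]
    return design


def residualize(table: CohortTable, covariate_names: list[str] | None = None,
                allow_missing_feature: bool = False) -> CohortTable:
    """Replace each feature by its standardized least-squares residual.

    Residuals are taken on intercept + covariates (categoricals expanded to
    treatment contrasts), then rescaled to mean 0 / sd 1. Missing feature
    values stay missing; rows with missing values are excluded from the fit
    and their residuals computed from the fitted coefficients.
    """
    covariate_names = covariate_names or list(table.schema.covariates)
    t = table.copy()
    design = _expand_covariates(t.data, covariate_names)
    for f in t.schema.features:
        y = t.data[f].to_numpy(dtype=float)
        obs = np.isfinite(y)
        if not obs.any():
            if allow_missing_feature:
                logger.warning("feature %r entirely missing; left for imputation", f)
                continue
            raise ValueError(f"feature {f!r} is entirely missing")
        beta, *_ = np.linalg.lstsq(design[obs], y[obs], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[obs] = y[obs] - design[obs] @ beta
        sd = np.nanstd(resid)
        if sd <= 1e-10 * max(np.nanstd(y[obs]), 1e-30):
            raise DegenerateScaleError(f"feature {f!r} has zero residual variance")
        t.data[f] = (resid - np.nanmean(resid)) / sd
    return t


def knn_impute(table: CohortTable, target: str, k: int = 5,
               ) -> tuple[CohortTable, pd.DataFrame]:
    """Fill missing values of ``target`` with the mean of its k nearest donors.

    Distance is Euclidean over the remaining (standardized, complete)
    features. Non-missing targets are untouched. Returns the imputed table
    and a per-row report of donor ids and distances.
    """
    t = table.copy()
    predictors = [f for f in t.schema.features if f != target]
    y = t.data[target].to_numpy(dtype=float)
    missing = ~np.isfinite(y)
    if not missing.any():
        return t, pd.DataFrame(columns=["row_id", "donor_ids", "donor_distances", "imputed"])
    X = t.data[predictors].to_numpy(dtype=float)
    row_bad = ~np.isfinite(X).all(axis=1)
    if (row_bad & missing).any():
        bad_ids = t.subject_ids[row_bad & missing].tolist()
        raise ValueError(f"all predictors missing for rows {bad_ids[:5]}")
    donors = np.flatnonzero(~missing & ~row_bad)
    if len(donors) < k:
        raise ValueError(f"only {len(donors)} donor rows available, need k={k}")
    report = []
    ids = t.subject_ids.to_numpy()
    for r in np.flatnonzero(missing):
        d = np.linalg.norm(X[donors] - X[r], axis=1)
        nearest = donors[np.argsort(d, kind="stable")[:k]]
        val = float(np.mean(y[nearest]))
        t.data.loc[t.data.index[r], target] = val
        report.append({
            "row_id": ids[r],
            "donor_ids": ",".join(map(str, ids[nearest])),
            "donor_distances": ",".join(f"{x:.6g}" for x in np.sort(d)[:k]),
            "imputed": val,
        })
    return t, pd.DataFrame(report)


def build_feature_matrix(table: CohortTable) -> FeatureMatrix:
    """Assemble the complete analysis matrix after preprocessing."""
    feats = table.features.copy()
    feats.index = pd.Index(table.subject_ids)
    return FeatureMatrix(feats, tuple(table.schema.features))
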