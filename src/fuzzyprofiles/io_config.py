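"""Run configuration, cohort table I/O, model serialization and seeding.

Cohort tables are delimited text (comma by default, tab accepted) with a
header row; missing values are empty fields or ``NA``. Profile models are
stored as versioned, human-readable JSON with full-precision floats so that
centroids fitted on one cohort can be shipped to and reused by another study.

A single global seed lives in :class:`RunConfig`; every stochastic stage
derives its own independent substream from it via :func:`substream`, so
reruns are byte-identical without per-stage seed bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fuzzyprofiles")

MODEL_FORMAT_VERSION = 1

#: canonical analysis features: three cognitive factors, three behavioral scales
DEFAULT_FEATURES = ("VA", "EFPS", "MEM", "internalizing", "externalizing", "stress")
COGNITIVE_FEATURES = ("VA", "EFPS", "MEM")
BEHAVIORAL_FEATURES = ("internalizing", "externalizing", "stress")


class SchemaError(ValueError):
    """A declared column is absent or mistyped."""


class IntegrityError(ValueError):
    """Table content violates an invariant (e.g. duplicate subject-timepoint)."""


@dataclass(frozen=True)
class RunConfig:
    """Global knobs shared by every pipeline stage.

    Parameters mirror the analysis defaults: fuzzifier m = 2, candidate
    cluster counts 2..10, 5000 graph permutations, 10,000 PLSR permutations,
    10-fold cross-validation, KNN imputation with k = 5 donors, and an FDR
    significance threshold of 0.05.
    """

    seed: int = 0
    fuzzifier: float = 2.0
    k_min: int = 2
    k_max: int = 10
    n_perm_graph: int = 5000
    n_perm_plsr: int = 10000
    cv_folds: int = 10
    knn_k: int = 5
    fdr_alpha: float = 0.05
    distance_transform: str = "one_minus_u"

    def __post_init__(self) -> None:
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        for name in ("k_min", "k_max", "n_perm_graph", "n_perm_plsr", "cv_folds", "knn_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.distance_transform not in ("one_minus_u", "neg_log_u"):
            raise ValueError(f"unknown distance_transform {self.distance_transform!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the global seed.

    The stage name is hashed into the spawn key, so streams for distinct
    stages are statistically independent and insensitive to call order.
    """
    key = np.frombuffer(stage.encode("utf-8"), dtype=np.uint8)
    ss = np.random.SeedSequence([int(seed), *key.tolist()])
    return np.random.default_rng(ss)


@dataclass
class CohortSchema:
    """Column-role mapping for a subject table."""

    subject_id: str = "subject_id"
    cohort: str = "cohort"
    timepoint: str = "timepoint"
    covariates: tuple[str, ...] = ("age", "sex", "ethnicity", "handedness")
    features: tuple[str, ...] = DEFAULT_FEATURES
    diagnoses: tuple[str, ...] = ()
    environment: tuple[str, ...] = ()

    def declared_columns(self) -> list[str]:
        return [
            self.subject_id,
            self.cohort,
            self.timepoint,
            *self.covariates,
            *self.features,
            *self.diagnoses,
            *self.environment,
        ]


@dataclass
class CohortTable:
    """Typed per-subject table: one row per subject per timepoint.

    ``data`` keeps the original row order; missingness is preserved as NaN.
    """

    data: pd.DataFrame
    schema: CohortSchema = field(default_factory=CohortSchema)

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.declared_columns() if c not in self.data.columns]
        if missing:
            raise SchemaError(f"declared columns absent from table: {missing}")
        key = self.data[[self.schema.subject_id, self.schema.timepoint]]
        dup = key.duplicated()
        if dup.any():
            first = key[dup].iloc[0].tolist()
            raise IntegrityError(f"duplicate subject_id x timepoint: {first}")
        for dx in self.schema.diagnoses:
            vals = self.data[dx].dropna().unique()
            bad = [v for v in vals if v not in (0, 1, 0.0, 1.0, True, False)]
            if bad:
                raise IntegrityError(f"diagnosis column {dx!r} has non-binary values {bad}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(self.schema.features)]

    @property
    def subject_ids(self) -> pd.Series:
        return self.data[self.schema.subject_id]

    def cohorts(self) -> list[str]:
        return list(pd.unique(self.data[self.schema.cohort]))

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.schema)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.schema)


def read_cohort_table(path: str | Path, schema: CohortSchema | None = None,
                      sep: str | None = None) -> CohortTable:
    """Read a delimited subject table and validate it against ``schema``.

    The delimiter is inferred from the extension (``.tsv`` -> tab) unless
    given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True)
    schema = schema or CohortSchema()
    return CohortTable(frame, schema)


def write_cohort_table(table: CohortTable, path: str | Path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False, na_rep="NA")


def write_profile_model(model, path: str | Path) -> None:
    """Serialize a fitted profile model to versioned JSON (lossless floats)."""
    from .fuzzy_profiles import ProfileModel  # local import avoids a cycle

    assert isinstance(model, ProfileModel)
    model.validate()
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "fuzzy_profile_model",
        "k": int(model.k),
        "fuzzifier": model.fuzzifier,
        "feature_names": list(model.feature_names),
        "labels": list(model.labels) if model.labels is not None else None,
        "centroids": [[float(v) for v in row] for row in model.centroids],
        "covariances": [[[float(v) for v in row] for row in cov] for cov in model.covariances],
        "objective": float(model.objective),
        "seed": model.seed,
        "n_iter": model.n_iter,
        "tol": model.tol,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_profile_model(path: str | Path):
    """Load a profile model written by :func:`write_profile_model`.

    Raises on version mismatch or invariant violations (e.g. a tampered
    non-symmetric covariance).
    """
    from .fuzzy_profiles import ProfileModel

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} not supported (expected {MODEL_FORMAT_VERSION})"
        )
    model = ProfileModel(
        centroids=np.asarray(doc["centroids"], dtype=float),
        covariances=[np.asarray(c, dtype=float) for c in doc["covariances"]],
        fuzzifier=float(doc["fuzzifier"]),
        feature_names=tuple(doc["feature_names"]),
        labels=tuple(doc["labels"]) if doc.get("labels") else None,
        objective=float(doc.get("objective", np.nan)),
        seed=doc.get("seed"),
        n_iter=doc.get("n_iter", 0),
        tol=doc.get("tol", 0.0),
    )
    model.validate()
    return model
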