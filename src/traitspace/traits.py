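"""Rating tables and per-subject trait vectors.

A subject's ratings of the item set are modeled as a linear readout of the
item embeddings: y_i ≈ X beta_i (+ intercept).  The coefficient vector
beta_i fitted on *all* of the subject's ratings is their **trait vector** —
a direction in embedding space summarizing what the subject values.  Because
a linear readout of unit-norm embeddings equals ``||beta||`` times the
cosine between beta and each item, the trait vector can be read as "the
item the subject is asking for".

Two statistics accompany each trait vector:

* ``precision_r`` — Pearson correlation between the full-data fit's
  predictions and the observed ratings; how well a single direction
  represents the subject at all.
* held-out CV r (via :func:`traitspace.ridge.cross_validate`) — honest
  predictive accuracy for unseen items.

The population-level model uses per-item mean ratings and the reserved
subject id ``"__mean__"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingMatrix
from .errors import (
    AlignmentError,
    InvalidInputError,
    InvalidRequestError,
    SchemaError,
    UndefinedAlignmentError,
    UndefinedCorrelationError,
)
from .ridge import CVReport, RidgeConfig, cross_validate, pearson_r, predict, ridge_fit

__all__ = [
    "DIMENSIONS",
    "MEAN_SUBJECT_ID",
    "RatingTable",
    "TraitVector",
    "TraitFitResult",
    "cosine_alignment",
    "fit_mean_model",
    "fit_trait_vector",
    "fit_all_traits",
    "read_rating_csv",
    "write_trait_csv",
    "read_trait_csv",
]

DIMENSIONS = ("like", "tasty", "healthy")
MEAN_SUBJECT_ID = "__mean__"

_RATING_COLUMNS = ["subject_id", "item_id", "dimension", "rating"]


class RatingTable:
    """Long-format Likert ratings: one row per (subject, item, dimension).

    Ratings are integers on a 1..`likert_levels` scale (default 8).  Missing
    (subject, item) pairs are simply absent rows; no imputation is done.
    """

    def __init__(self, df: pd.DataFrame, likert_levels: int = 8,
                 dimensions: Sequence[str] = DIMENSIONS):
        if likert_levels < 2:
            raise InvalidInputError("likert_levels must be at least 2")
        if list(df.columns) != _RATING_COLUMNS:
            raise SchemaError(f"rating table columns must be {_RATING_COLUMNS}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        df["dimension"] = df["dimension"].astype(str)
        bad_dim = set(df["dimension"]) - set(dimensions)
        if bad_dim:
            raise SchemaError(f"unknown rating dimensions {sorted(bad_dim)}")
        ratings = pd.to_numeric(df["rating"], errors="coerce")
        if ratings.isna().any():
            raise SchemaError("non-numeric ratings")
        if ((ratings < 1) | (ratings > likert_levels)).any():
            raise SchemaError(f"ratings outside 1..{likert_levels}")
        if (ratings != ratings.round()).any():
            raise SchemaError("ratings must be integers")
        df["rating"] = ratings.astype(int)
        dup = df.duplicated(subset=["subject_id", "item_id", "dimension"])
        if dup.any():
            raise SchemaError("duplicate (subject, item, dimension) records")
        self.df = df.reset_index(drop=True)
        self.likert_levels = int(likert_levels)
        self.dimensions = tuple(dimensions)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def item_ids(self) -> list[str]:
        return sorted(self.df["item_id"].unique())

    def has_dimension(self, dimension: str) -> bool:
        return bool((self.df["dimension"] == dimension).any())

    def mean_ratings(self, dimension: str) -> tuple[list[str], np.ndarray]:
        """Per-item mean rating across subjects, items sorted by id."""
        sub = self.df[self.df["dimension"] == dimension]
        if sub.empty:
            raise InvalidRequestError(f"no ratings for dimension {dimension!r}")
        g = sub.groupby("item_id")["rating"].mean().sort_index()
        return list(g.index), g.to_numpy(float)

    def subject_ratings(self, subject_id: str, dimension: str) -> tuple[list[str], np.ndarray]:
        sub = self.df[(self.df["subject_id"] == str(subject_id))
                      & (self.df["dimension"] == dimension)]
        if sub.empty:
            raise InvalidRequestError(
                f"no {dimension!r} ratings for subject {subject_id!r}")
        sub = sub.sort_values("item_id")
        return sub["item_id"].tolist(), sub["rating"].to_numpy(float)

    def rescale(self, y: np.ndarray, config: RidgeConfig) -> np.ndarray:
        """Apply the configured rating rescale (Likert range → [0, 1])."""
        if config.rating_rescale == "unit_interval":
            return (np.asarray(y, float) - 1.0) / (self.likert_levels - 1.0)
        return np.asarray(y, float)


@dataclass
class TraitVector:
    """Per-(subject, dimension) ridge coefficients with fit statistics.

    ``beta`` excludes the intercept: it is the direction in embedding space;
    the intercept is stored separately.  ``precision_r`` is defined only for
    full-data fits and is NaN when the subject's ratings were constant.
    """

    subject_id: str
    dimension: str
    beta: np.ndarray
    intercept: float
    precision_r: float = float("nan")
    lambda_used: float = 1.0
    fit_scope: str = "full_data"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.isfinite(self.beta).all():
            raise InvalidInputError("non-finite trait coefficients")
        if self.fit_scope not in ("full_data", "cv_train_fold"):
            raise InvalidInputError(f"unknown fit_scope {self.fit_scope!r}")

    @property
    def precision_defined(self) -> bool:
        return not math.isnan(self.precision_r)


@dataclass
class TraitFitResult:
    """Output of :func:`fit_all_traits`: traits, per-subject CV, failures."""

    traits: list[TraitVector]
    cv_reports: dict[str, CVReport]
    failures: dict[str, str]


def cosine_alignment(v: np.ndarray, w: np.ndarray) -> float:
    """Cosine of the angle between two vectors; raises on a zero vector."""
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if v.shape != w.shape:
        raise InvalidInputError("vector length mismatch")
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        raise UndefinedAlignmentError("cosine alignment undefined for a zero vector")
    return float(np.clip(v @ w / (nv * nw), -1.0, 1.0))


def _aligned_design(E: EmbeddingMatrix, item_ids: Sequence[str]) -> np.ndarray:
    missing = set(item_ids) - set(E.item_ids)
    if missing:
        raise AlignmentError(f"items missing from embedding: {sorted(missing)[:5]}")
    return E.rows(item_ids)


def _safe_precision(observed: np.ndarray, predicted: np.ndarray) -> float:
    try:
        return pearson_r(predicted, observed)
    except UndefinedCorrelationError:
        return float("nan")


def fit_mean_model(E: EmbeddingMatrix, R: RatingTable, dimension: str,
                   config: RidgeConfig = RidgeConfig()) -> tuple[TraitVector, CVReport]:
    """Fit the population model on per-item mean ratings.

    Returns the full-data trait vector under the reserved subject id
    ``"__mean__"`` together with a k-fold cross-validation report.
    """
    if not R.has_dimension(dimension):
        raise InvalidRequestError(f"dimension {dimension!r} absent from ratings")
    item_ids, y_raw = R.mean_ratings(dimension)
    X = _aligned_design(E, item_ids)
    y = R.rescale(y_raw, config)
    beta, b0 = ridge_fit(X, y, config)
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True) \
        if config.feature_normalize == "unit_rows" else X
    trait = TraitVector(MEAN_SUBJECT_ID, dimension, beta, b0,
                        _safe_precision(y, Xn @ beta + b0),
                        config.lam, "full_data")
    report = cross_validate(X, y, config, item_ids=item_ids)
    return trait, report


def fit_trait_vector(E: EmbeddingMatrix, R: RatingTable, subject_id: str,
                     dimension: str, config: RidgeConfig = RidgeConfig()) -> TraitVector:
    """Fit one subject's trait vector on all of their ratings.

    No data are held out: the trait vector is deliberately the most stable
    representation of the subject, and ``precision_r`` measures in-sample
    fit.  Held-out accuracy comes from :func:`traitspace.ridge.cross_validate`
    (see :func:`fit_all_traits`).
    """
    item_ids, y_raw = R.subject_ratings(subject_id, dimension)
    if len(item_ids) < 3:
        raise InvalidRequestError(
            f"subject {subject_id!r} has only {len(item_ids)} ratings; need >= 3")
    X = _aligned_design(E, item_ids)
    y = R.rescale(y_raw, config)
    beta, b0 = ridge_fit(X, y, config)
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True) \
        if config.feature_normalize == "unit_rows" else X
    return TraitVector(str(subject_id), dimension, beta, b0,
                       _safe_precision(y, Xn @ beta + b0),
                       config.lam, "full_data")


def fit_all_traits(E: EmbeddingMatrix, R: RatingTable, dimension: str,
                   config: RidgeConfig = RidgeConfig()) -> TraitFitResult:
    """Fit every subject's trait vector plus a per-subject CV report.

    Subjects are processed in sorted id order with a shared seed; subjects
    whose data cannot be fitted are reported in ``failures``, never silently
    dropped.
    """
    traits: list[TraitVector] = []
    reports: dict[str, CVReport] = {}
    failures: dict[str, str] = {}
    subjects = sorted(set(R.df.loc[R.df["dimension"] == dimension, "subject_id"]))
    for sid in subjects:
        try:
            traits.append(fit_trait_vector(E, R, sid, dimension, config))
            item_ids, y_raw = R.subject_ratings(sid, dimension)
            X = _aligned_design(E, item_ids)
            reports[sid] = cross_validate(X, R.rescale(y_raw, config), config,
                                          item_ids=item_ids)
        except (InvalidRequestError, AlignmentError, InvalidInputError) as exc:
            failures[sid] = str(exc)
    return TraitFitResult(traits, reports, failures)


# ---------------------------------------------------------------------------
# file formats

_FLOAT_FMT = "%.17g"


def read_rating_csv(path: str | Path, likert_levels: int = 8,
                    dimensions: Sequence[str] = DIMENSIONS) -> RatingTable:
    """Read a long-format rating CSV with strict header validation."""
    df = pd.read_csv(path, dtype={"subject_id": str, "item_id": str})
    if list(df.columns) != _RATING_COLUMNS:
        raise SchemaError(
            f"rating CSV header must be {','.join(_RATING_COLUMNS)}; got {list(df.columns)}")
    return RatingTable(df, likert_levels=likert_levels, dimensions=dimensions)


def write_rating_csv(R: RatingTable, path: str | Path) -> None:
    R.df.to_csv(path, index=False)


def write_trait_csv(traits: Sequence[TraitVector], path: str | Path) -> None:
    """``subject_id,dimension,intercept,precision_r,lambda,b0..b{d-1}`` CSV."""
    if not traits:
        raise InvalidRequestError("no trait vectors to write")
    dims = traits[0].beta.shape[0]
    rows = []
    for t in traits:
        if t.beta.shape[0] != dims:
            raise InvalidInputError("trait vectors of mixed dimensionality")
        rows.append([t.subject_id, t.dimension, t.intercept, t.precision_r,
                     t.lambda_used, *t.beta])
    cols = ["subject_id", "dimension", "intercept", "precision_r", "lambda",
            *[f"b{j}" for j in range(dims)]]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trait_csv(path: str | Path) -> list[TraitVector]:
    df = pd.read_csv(path, dtype={"subject_id": str, "dimension": str})
    head = ["subject_id", "dimension", "intercept", "precision_r", "lambda"]
    if list(df.columns[:5]) != head:
        raise SchemaError(f"trait CSV must start with columns {head}")
    bcols = [c for c in df.columns[5:]]
    if bcols != [f"b{j}" for j in range(len(bcols))]:
        raise SchemaError("trait CSV coefficient columns must be b0,b1,...")
    out = []
    for _, row in df.iterrows():
        out.append(TraitVector(
            row["subject_id"], row["dimension"],
            row[bcols].to_numpy(float), float(row["intercept"]),
            float(row["precision_r"]), float(row["lambda"]), "full_data"))
    return out
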