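"""Ridge regression engine: closed-form fit, k-fold CV, regularization path.

The rating models throughout the package are ridge regressions

    min_beta ||y - X beta||^2 + lambda ||beta||^2

with the penalty exactly ``lambda * ||beta||^2`` (no scaling by the number of
items).  The solve uses the singular-value decomposition of the (optionally
column-centered) design, which is stable when dims is comparable to or larger
than the number of items — the regime of interest, where a few hundred rated
items meet an embedding of similar dimensionality.

An unpenalized intercept is fitted by centering, since Likert ratings are not
zero-centered; it can be switched off to match the bare linear form y = X b.
Ratings are by default mapped from the Likert range onto [0, 1] before
fitting (``rating_rescale="unit_interval"``); all reported MSEs are on the
fitted scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr as _scipy_pearsonr

from ._rng import stage_rng
from .errors import InvalidInputError, InvalidRequestError, UndefinedCorrelationError

__all__ = [
    "RidgeConfig",
    "CVReport",
    "ridge_fit",
    "predict",
    "cross_validate",
    "lambda_sweep_one_se",
    "pearson_r",
]


@dataclass(frozen=True)
class RidgeConfig:
    """Configuration shared by every ridge fit in an analysis.

    Attributes
    ----------
    lam:
        Ridge penalty λ ≥ 0.  Default 1.0, a conservative choice that trades
        a little held-out accuracy for stable coefficient directions —
        exactly what trait-vector extraction needs.
    fit_intercept:
        Fit an unpenalized intercept via centering (default True).
    n_folds:
        Folds for cross-validation (default 5).
    seed:
        Seed for the fold partition.
    feature_normalize:
        ``"none"`` or ``"unit_rows"`` (L2-normalize embedding rows first).
    rating_rescale:
        ``"none"`` or ``"unit_interval"`` (map the Likert range to [0, 1]).
    """

    lam: float = 1.0
    fit_intercept: bool = True
    n_folds: int = 5
    seed: int = 0
    feature_normalize: str = "none"
    rating_rescale: str = "unit_interval"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise InvalidInputError("lambda must be non-negative")
        if self.n_folds < 2:
            raise InvalidInputError("n_folds must be at least 2")
        if self.feature_normalize not in ("none", "unit_rows"):
            raise InvalidInputError(f"unknown feature_normalize {self.feature_normalize!r}")
        if self.rating_rescale not in ("none", "unit_interval"):
            raise InvalidInputError(f"unknown rating_rescale {self.rating_rescale!r}")


@dataclass
class CVReport:
    """Per-fold MSE and Pearson r for one model configuration.

    ``per_fold_r`` holds NaN for folds whose held-out ratings were constant
    (correlation undefined there); those fold indices are listed in
    ``undefined_r_folds``.  Summary statistics are computed over defined
    folds only.
    """

    lam: float
    n_folds: int
    seed: int
    per_fold_mse: list[float]
    per_fold_r: list[float]
    fold_assignment: dict[str, int]
    undefined_r_folds: list[int] = field(default_factory=list)

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.per_fold_mse))

    @property
    def sd_mse(self) -> float:
        return float(np.std(self.per_fold_mse, ddof=1)) if self.n_folds > 1 else 0.0

    @property
    def mean_r(self) -> float:
        vals = [r for r in self.per_fold_r if not math.isnan(r)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd_r(self) -> float:
        vals = [r for r in self.per_fold_r if not math.isnan(r)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    def to_dict(self) -> dict:
        def _clean(x: float):
            return None if math.isnan(x) else x

        return {
            "lambda": self.lam,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_fold_mse": list(self.per_fold_mse),
            "per_fold_r": [_clean(r) for r in self.per_fold_r],
            "undefined_r_folds": list(self.undefined_r_folds),
            "mean_mse": self.mean_mse,
            "sd_mse": self.sd_mse,
            "mean_r": _clean(self.mean_r),
            "sd_r": _clean(self.sd_r),
            "fold_assignment": dict(sorted(self.fold_assignment.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise InvalidInputError("X must be 2-D")
    if X.shape[1] == 0:
        raise InvalidInputError("X has zero feature dimensions")
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError(f"{X.shape[0]} rows of X but {y.shape[0]} targets")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise InvalidInputError("non-finite values in X or y")
    return X, y


def ridge_fit(X: np.ndarray, y: np.ndarray,
              config: RidgeConfig = RidgeConfig()) -> tuple[np.ndarray, float]:
    """Solve the ridge objective; return ``(beta, intercept)``.

    With ``fit_intercept`` the problem is solved on column- and y-centered
    data and the intercept recovered afterwards, so it is not shrunk.  At
    ``lam == 0`` the minimum-norm least-squares solution is returned
    (singular directions get zero coefficients).
    """
    X, y = _validate_xy(X, y)
    if config.feature_normalize == "unit_rows":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if (norms == 0).any():
            raise InvalidInputError("cannot unit-normalize a zero embedding row")
        X = X / norms
    if config.fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc, yc = X - x_mean, y - y_mean
    else:
        x_mean = np.zeros(X.shape[1])
        y_mean = 0.0
        Xc, yc = X, y
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if config.lam > 0:
        shrink = s / (s * s + config.lam)
    else:
        tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        shrink = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0), 0.0)
    beta = Vt.T @ (shrink * (U.T @ yc))
    intercept = y_mean - float(x_mean @ beta) if config.fit_intercept else 0.0
    return beta, intercept


def predict(X: np.ndarray, beta: np.ndarray, intercept: float = 0.0) -> np.ndarray:
    """Linear readout ``X @ beta + intercept``."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise InvalidInputError(
            f"shape mismatch: X is {X.shape}, beta has {beta.shape[0]} entries")
    return X @ beta + float(intercept)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation; raises on constant input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidInputError("length mismatch")
    if a.size < 2:
        raise InvalidInputError("need at least 2 points")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(_scipy_pearsonr(a, b)[0])


def fold_partition(n_items: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded uniform random partition; fold sizes differ by at most 1."""
    rng = stage_rng(seed, "cv_fold_partition")
    perm = rng.permutation(n_items)
    folds = np.empty(n_items, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = k
    return folds


def cross_validate(X: np.ndarray, y: np.ndarray, config: RidgeConfig = RidgeConfig(),
                   item_ids: Sequence[str] | None = None) -> CVReport:
    """k-fold cross-validation of the ridge model.

    Items are partitioned at random (seeded); each fold is scored by MSE and
    Pearson r between held-out observations and predictions.  A fold whose
    held-out ratings are constant gets ``r = NaN`` and is flagged, never
    silently zeroed.
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if n < config.n_folds:
        raise InvalidRequestError(f"{n} items cannot fill {config.n_folds} folds")
    ids = [str(i) for i in (item_ids if item_ids is not None else range(n))]
    if len(ids) != n:
        raise InvalidInputError("item_ids length mismatch")
    folds = fold_partition(n, config.n_folds, config.seed)
    per_mse: list[float] = []
    per_r: list[float] = []
    undefined: list[int] = []
    for k in range(config.n_folds):
        test = folds == k
        beta, b0 = ridge_fit(X[~test], y[~test], config)
        Xt = X[test]
        if config.feature_normalize == "unit_rows":
            Xt = Xt / np.linalg.norm(Xt, axis=1, keepdims=True)
        yhat = Xt @ beta + b0
        per_mse.append(float(np.mean((y[test] - yhat) ** 2)))
        try:
            per_r.append(pearson_r(y[test], yhat))
        except UndefinedCorrelationError:
            per_r.append(float("nan"))
            undefined.append(k)
    assignment = {ids[i]: int(folds[i]) for i in range(n)}
    return CVReport(config.lam, config.n_folds, config.seed,
                    per_mse, per_r, assignment, undefined)


def lambda_sweep_one_se(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float],
    config: RidgeConfig = RidgeConfig(),
) -> tuple[float, float, dict[float, CVReport]]:
    """CV over a λ grid; return ``(lambda_min, lambda_one_se, path)``.

    ``lambda_min`` minimizes mean CV MSE.  ``lambda_one_se`` is the largest
    grid value whose mean CV MSE stays within one standard error (sd of the
    minimizing λ's fold MSEs divided by √n_folds) of the minimum — the
    classic parsimony rule that prefers stronger regularization when the
    error curve is flat.  All grid points share one fold partition.
    """
    grid = [float(l) for l in lambda_grid]
    if not grid:
        raise InvalidRequestError("empty lambda grid")
    if any(l <= 0 for l in grid):
        raise InvalidInputError("lambda grid must be positive")
    if sorted(grid) != grid:
        raise InvalidRequestError("lambda grid must be sorted ascending")
    path = {l: cross_validate(X, y, replace(config, lam=l)) for l in grid}
    means = np.array([path[l].mean_mse for l in grid])
    i_min = int(np.argmin(means))
    lam_min = grid[i_min]
    se = float(np.std(path[lam_min].per_fold_mse, ddof=1)) / math.sqrt(config.n_folds)
    threshold = means[i_min] + se
    eligible = [l for l, m in zip(grid, means) if m <= threshold + 1e-15]
    return lam_min, max(eligible), path
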