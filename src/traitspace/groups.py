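"""Group splits and nonparametric group-difference tests.

Subjects carry questionnaire scores — a picky-eating score and a broad
psychopathology (DSM-style) score.  Subjects are split at an empirical
quantile of a score (median by default; the cut is a configurable analysis
choice, not a clinical threshold), and two kinds of group differences are
tested:

* **precision differences** — do high scorers' ratings conform less well to
  a single trait direction?  Tested on per-subject ``precision_r`` values
  with a Mann-Whitney U test (exact enumeration for small samples, tie- and
  continuity-corrected normal approximation otherwise).
* **direction bias** — are high scorers' trait vectors further from a
  reference direction (e.g. the population "healthy" model)?  Tested with a
  seeded permutation test on the low-minus-high gap in mean cosine
  alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._rng import stage_rng
from .errors import (
    DegenerateSplitError,
    InvalidInputError,
    InvalidRequestError,
    SchemaError,
    UndefinedAlignmentError,
)
from .traits import TraitVector, cosine_alignment

__all__ = [
    "GroupTestResult",
    "split_groups",
    "mann_whitney_u",
    "precision_group_test",
    "direction_bias_test",
    "read_subject_scores",
    "write_subject_scores",
]

SCORE_COLUMNS = ["subject_id", "picky_score", "dsm_score"]

#: combined sample size at or below which the exact null is enumerated
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class GroupTestResult:
    """Outcome of a two-sample rank test."""

    statistic: float
    p_value: float
    method: str  # "exact_enumeration" | "normal_approx"
    group_sizes: tuple[int, int]
    alternative: str  # "two_sided" | "less" | "greater"
    excluded_subjects: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "group_sizes": list(self.group_sizes),
            "alternative": self.alternative,
            "excluded_subjects": list(self.excluded_subjects),
        }


def split_groups(scores: pd.DataFrame, score_field: str,
                 quantile: float = 0.5) -> dict[str, str]:
    """Assign each subject to ``"low"`` or ``"high"`` by an empirical quantile.

    Subjects strictly above the quantile of ``score_field`` go to ``high``;
    ties with the quantile value go to ``low`` (deterministic strictly-above
    rule).
    """
    if not 0.0 < quantile < 1.0:
        raise InvalidRequestError("quantile must lie in (0, 1)")
    if score_field not in scores.columns:
        raise InvalidRequestError(f"unknown score field {score_field!r}")
    if len(scores) < 2:
        raise InvalidRequestError("need at least 2 subjects to split")
    vals = scores[score_field].to_numpy(float)
    if not np.isfinite(vals).all():
        raise InvalidInputError("non-finite questionnaire scores")
    if np.ptp(vals) == 0.0:
        raise DegenerateSplitError(f"{score_field} is constant; no split possible")
    cut = float(np.quantile(vals, quantile))
    return {str(s): ("high" if v > cut else "low")
            for s, v in zip(scores["subject_id"], vals)}


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{(i,j): a_i > b_j} + half-counting of ties."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    n_a = a.size
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   alternative: str = "two_sided",
                   method: str = "auto") -> GroupTestResult:
    """Mann-Whitney U test of two independent samples.

    The statistic is U for sample ``a``: the number of pairs with
    ``a_i > b_j`` plus one half per tied pair.  When the combined sample is
    small (n ≤ 12) the p-value is computed by full enumeration of all
    group assignments of the pooled data, which handles ties exactly;
    otherwise a normal approximation with tie-corrected variance and a
    continuity correction is used.  ``method`` may force ``"exact"`` or
    ``"normal"``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidRequestError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidInputError("non-finite sample values")
    if alternative not in ("two_sided", "less", "greater"):
        raise InvalidRequestError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "normal"):
        raise InvalidRequestError(f"unknown method {method!r}")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    u_obs = _u_statistic(a, b)
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_ENUMERATION_LIMIT)
    mu = n_a * n_b / 2.0
    if use_exact:
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        offset = n_a * (n_a + 1) / 2.0
        us = np.array([ranks[list(idx)].sum() - offset
                       for idx in combinations(range(n), n_a)])
        eps = 1e-9
        if alternative == "greater":
            p = float(np.mean(us >= u_obs - eps))
        elif alternative == "less":
            p = float(np.mean(us <= u_obs + eps))
        else:
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps))
        return GroupTestResult(u_obs, min(p, 1.0), "exact_enumeration",
                               (n_a, n_b), alternative)
    # normal approximation with tie correction and continuity correction
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        # all pooled values identical: no evidence either way
        return GroupTestResult(u_obs, 1.0, "normal_approx", (n_a, n_b), alternative)
    sigma = math.sqrt(sigma2)
    if alternative == "greater":
        p = float(norm.sf((u_obs - mu - 0.5) / sigma))
    elif alternative == "less":
        p = float(norm.cdf((u_obs - mu + 0.5) / sigma))
    else:
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = float(2.0 * norm.sf(max(z, 0.0)))
    return GroupTestResult(u_obs, min(p, 1.0), "normal_approx",
                           (n_a, n_b), alternative)


def precision_group_test(traits: Iterable[TraitVector], groups: Mapping[str, str],
                         dimension: str,
                         alternative: str = "two_sided") -> GroupTestResult:
    """Mann-Whitney test of per-subject precision_r between low and high groups.

    Subjects whose precision is undefined (constant ratings) are excluded and
    reported in ``excluded_subjects``, never dropped silently.
    """
    low, high, excluded = [], [], []
    for t in traits:
        if t.dimension != dimension or t.subject_id not in groups:
            continue
        if not t.precision_defined:
            excluded.append(t.subject_id)
            continue
        (low if groups[t.subject_id] == "low" else high).append(t.precision_r)
    if not low or not high:
        raise InvalidRequestError("both groups must contain a subject with "
                                  f"defined precision for {dimension!r}")
    res = mann_whitney_u(low, high, alternative=alternative)
    res.excluded_subjects = tuple(sorted(excluded))
    return res


def direction_bias_test(traits_low: Sequence[TraitVector],
                        traits_high: Sequence[TraitVector],
                        reference_direction: np.ndarray,
                        n_permutations: int = 10_000,
                        seed: int = 0,
                        alternative: str = "two_sided") -> tuple[float, float]:
    """Permutation test for a group difference in alignment with a reference.

    Each subject's trait vector is reduced to its cosine alignment with
    ``reference_direction``; the observed statistic is the low-group mean
    minus the high-group mean (positive when the high group points further
    away from the reference).  The null is built by permuting group labels
    ``n_permutations`` times (seeded); the p-value uses add-one smoothing
    ``(b + 1) / (m + 1)`` so it is never exactly zero.

    Returns ``(observed_gap, p_value)``.
    """
    ref = np.asarray(reference_direction, dtype=float).ravel()
    if np.linalg.norm(ref) == 0.0:
        raise UndefinedAlignmentError("zero reference direction")
    if n_permutations < 1:
        raise InvalidRequestError("n_permutations must be positive")
    if not traits_low or not traits_high:
        raise InvalidRequestError("both groups must be non-empty")
    align_low = np.array([cosine_alignment(t.beta, ref) for t in traits_low])
    align_high = np.array([cosine_alignment(t.beta, ref) for t in traits_high])
    gap = float(align_low.mean() - align_high.mean())
    pooled = np.concatenate([align_low, align_high])
    n_low = align_low.size
    rng = stage_rng(seed, "direction_bias_permutation")
    # vectorized label permutations
    order = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
    perm = pooled[order]
    gaps = perm[:, :n_low].mean(axis=1) - perm[:, n_low:].mean(axis=1)
    eps = 1e-12
    if alternative == "greater":
        b = int(np.sum(gaps >= gap - eps))
    elif alternative == "less":
        b = int(np.sum(gaps <= gap + eps))
    elif alternative == "two_sided":
        b = int(np.sum(np.abs(gaps) >= abs(gap) - eps))
    else:
        raise InvalidRequestError(f"unknown alternative {alternative!r}")
    return gap, (b + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# file format: subject_id,picky_score,dsm_score


def read_subject_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != SCORE_COLUMNS:
        raise SchemaError(f"subject-scores CSV header must be {','.join(SCORE_COLUMNS)}")
    if df["subject_id"].duplicated().any():
        raise SchemaError("duplicate subject ids in scores file")
    for c in SCORE_COLUMNS[1:]:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise SchemaError(f"non-numeric values in {c}")
        df[c] = vals.astype(float)
    return df


def write_subject_scores(df: pd.DataFrame, path: str | Path) -> None:
    if list(df.columns) != SCORE_COLUMNS:
        raise SchemaError(f"subject-scores columns must be {SCORE_COLUMNS}")
    df.to_csv(path, index=False, float_format="%.17g")
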