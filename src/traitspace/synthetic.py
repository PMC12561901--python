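"""Synthetic rating-study generator with known ground truth.

The generator builds a miniature world with the statistical structure the
analysis assumes, so every estimator in the package can be tested against
truth:

* **items** live on the unit sphere in R^dims, clustered around category
  centroids (food categories produce visible structure in real embedding
  spaces; unit norm makes the cosine and linear readings of a trait vector
  exactly equivalent);
* **subjects** carry one true trait vector per rating dimension (like,
  tasty, healthy), built from a population direction plus an individual
  component, with the three dimensions correlated within subject;
* **ratings** are a noisy affine function of item·trait, discretized onto a
  1..8 Likert scale;
* **group effects**: a "picky" subgroup has its like/tasty traits rotated
  away from the healthy reference direction (their preferences decouple
  from healthiness), and a "high-DSM" subgroup rates with inflated noise
  (their ratings conform less to any single direction) — the two group-level
  phenomena the analysis is meant to detect.

Default sizes mirror the study design this testbed emulates (896 items, 199
subjects, 8-point Likert scale); effect sizes are calibration choices, since
no quantitative values exist for them.  Everything is reproducible from one
seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .embeddings import EmbeddingMatrix, write_embedding_csv
from .errors import InvalidInputError, InvalidRequestError
from .groups import SCORE_COLUMNS, write_subject_scores
from .traits import DIMENSIONS, RatingTable
from .traits import write_rating_csv

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_embedding_space",
    "generate_subjects",
    "generate_ratings",
    "generate_subject_scores",
    "simulate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic world.

    ``n_items``, ``n_subjects`` and ``likert_levels`` default to the
    emulated study design (896 images, 199 raters, 8-point scale).  The
    latent rating scale is the unit interval: ``latent = rating_slope *
    (item · trait) + rating_offset + noise`` with defaults mapping the
    cosine range [-1, 1] onto [0, 1], after which the latent is mapped
    affinely onto 1..likert_levels, rounded half-up and clipped.
    ``noise_sd`` is therefore expressed on the unit-interval scale.
    """

    n_items: int = 896
    n_subjects: int = 199
    dims: int = 64
    n_categories: int = 16
    cluster_concentration: float = 4.0
    rating_slope: float = 0.5
    rating_offset: float = 0.5
    noise_sd: float = 0.3
    likert_levels: int = 8
    population_direction_weight: float = 0.5
    trait_dimension_corr: float = 0.5
    healthy_alignment: float = 0.6
    picky_fraction: float = 0.15
    dsm_fraction: float = 0.15
    picky_rotation_deg: float = 45.0
    dsm_noise_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.likert_levels < 2:
            raise InvalidRequestError("likert_levels must be at least 2")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if not 0.0 <= self.population_direction_weight <= 1.0:
            raise InvalidInputError("population_direction_weight must be in [0, 1]")
        if not 0.0 <= self.picky_fraction <= 1.0 or not 0.0 <= self.dsm_fraction <= 1.0:
            raise InvalidInputError("group fractions must be in [0, 1]")
        if self.picky_fraction + self.dsm_fraction > 1.0:
            raise InvalidRequestError("group fractions sum above 1")
        if self.dsm_noise_multiplier < 1.0:
            raise InvalidInputError("dsm_noise_multiplier must be >= 1")
        if self.cluster_concentration <= 0:
            raise InvalidInputError("cluster_concentration must be positive")


@dataclass
class GroundTruth:
    """The synthetic world's hidden state, for recovery testing."""

    true_traits: dict[str, dict[str, np.ndarray]]  # subject -> dimension -> vector
    group_labels: dict[str, str]  # subject -> control | picky_high | dsm_high
    item_categories: dict[str, int]
    healthy_direction: np.ndarray
    subject_noise_sd: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "healthy_direction": list(map(float, self.healthy_direction)),
            "group_labels": self.group_labels,
            "item_categories": {k: int(v) for k, v in self.item_categories.items()},
            "subject_noise_sd": self.subject_noise_sd,
            "true_traits": {s: {d: list(map(float, v)) for d, v in dims.items()}
                            for s, dims in self.true_traits.items()},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_traits={s: {d: np.asarray(v, float) for d, v in dims.items()}
                         for s, dims in payload["true_traits"].items()},
            group_labels=payload["group_labels"],
            item_categories=payload["item_categories"],
            healthy_direction=np.asarray(payload["healthy_direction"], float),
            subject_noise_sd=payload["subject_noise_sd"],
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator, dims: int) -> np.ndarray:
    return _unit(rng.standard_normal(dims))


def generate_embedding_space(config: SyntheticConfig) -> tuple[EmbeddingMatrix, dict[str, int]]:
    """Clustered unit-sphere item embeddings.

    Category centroids are uniform on the sphere; each item is its centroid
    plus isotropic noise of scale ``1 / cluster_concentration``,
    re-normalized to unit length.  Larger concentration means tighter,
    better-separated categories.
    """
    if config.dims < 2:
        raise InvalidRequestError("dims must be at least 2")
    if config.n_categories > config.n_items:
        raise InvalidRequestError("more categories than items")
    rng = stage_rng(config.seed, "embedding_space")
    centroids = np.stack([_random_unit(rng, config.dims)
                          for _ in range(config.n_categories)])
    cats = rng.integers(0, config.n_categories, size=config.n_items)
    noise = rng.standard_normal((config.n_items, config.dims)) / config.cluster_concentration
    vecs = centroids[cats] + noise
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    width = len(str(config.n_items - 1))
    ids = [f"item{str(i).zfill(width)}" for i in range(config.n_items)]
    E = EmbeddingMatrix(ids, vecs, provider_tag="synthetic")
    return E, {ids[i]: int(cats[i]) for i in range(config.n_items)}


def _rotate_from_reference(trait: np.ndarray, reference: np.ndarray,
                           delta_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Increase the angle between ``trait`` and ``reference`` by ``delta_deg``.

    The rotation stays in the plane spanned by the two vectors and is capped
    at orthogonality (90 deg): the planted effect models indifference toward
    the reference axis, not active avoidance.  If the trait is (anti)parallel
    to the reference the rotation plane is degenerate and a random
    orthogonal complement is used instead.
    """
    u = _unit(reference)
    c = float(trait @ u)
    perp = trait - c * u
    norm_perp = np.linalg.norm(perp)
    if norm_perp < 1e-12:
        w = rng.standard_normal(trait.shape[0])
        w -= (w @ u) * u
        t_perp = _unit(w)
        norm_perp = 0.0
    else:
        t_perp = perp / norm_perp
    theta = math.atan2(norm_perp, c)  # angle from reference, in [0, pi]
    theta_new = min(theta + math.radians(delta_deg), math.pi / 2.0)
    theta_new = max(theta_new, theta)  # never rotate back toward the reference
    r = np.linalg.norm(trait)
    return r * (math.cos(theta_new) * u + math.sin(theta_new) * t_perp)


def generate_subjects(config: SyntheticConfig,
                      healthy_direction: np.ndarray | None = None) -> GroundTruth:
    """Draw ground-truth traits, group labels and per-subject noise levels.

    Per dimension there is one population direction; a subject's trait is
    ``w * population + (1 - w) * individual`` (normalized), with the three
    dimensions' individual components correlated within subject
    (``trait_dimension_corr``).  The healthy population direction *is* the
    healthy reference; the like/tasty population directions are drawn with
    cosine ``healthy_alignment`` to it, reflecting that average preference
    correlates positively with perceived healthiness — which gives the picky
    rotation room to move traits away from the healthy axis.
    """
    rng = stage_rng(config.seed, "subjects")
    d = config.dims
    healthy = _unit(np.asarray(healthy_direction, float)) \
        if healthy_direction is not None else _random_unit(rng, d)

    def _aligned_direction(target_cos: float) -> np.ndarray:
        w = rng.standard_normal(d)
        w -= (w @ healthy) * healthy
        return _unit(target_cos * healthy + math.sqrt(1 - target_cos**2) * _unit(w))

    population = {
        "healthy": healthy,
        "like": _aligned_direction(config.healthy_alignment),
        "tasty": _aligned_direction(config.healthy_alignment),
    }

    n = config.n_subjects
    width = len(str(max(n - 1, 1)))
    sids = [f"s{str(i).zfill(width)}" for i in range(n)]

    n_picky = int(round(config.picky_fraction * n))
    n_dsm = int(round(config.dsm_fraction * n))
    order = rng.permutation(n)
    labels = {}
    for rank, idx in enumerate(order):
        if rank < n_picky:
            labels[sids[idx]] = "picky_high"
        elif rank < n_picky + n_dsm:
            labels[sids[idx]] = "dsm_high"
        else:
            labels[sids[idx]] = "control"

    w = config.population_direction_weight
    rho = config.trait_dimension_corr
    traits: dict[str, dict[str, np.ndarray]] = {}
    noise: dict[str, float] = {}
    for sid in sids:
        base = _random_unit(rng, d)
        per_dim: dict[str, np.ndarray] = {}
        for dim in DIMENSIONS:
            indiv = _unit(rho * base + math.sqrt(1 - rho**2) * _random_unit(rng, d))
            t = _unit(w * population[dim] + (1 - w) * indiv) if w < 1.0 \
                else population[dim].copy()
            per_dim[dim] = t
        if labels[sid] == "picky_high" and config.picky_rotation_deg != 0.0:
            for dim in ("like", "tasty"):
                per_dim[dim] = _rotate_from_reference(
                    per_dim[dim], healthy, config.picky_rotation_deg, rng)
        traits[sid] = per_dim
        noise[sid] = config.noise_sd * (config.dsm_noise_multiplier
                                        if labels[sid] == "dsm_high" else 1.0)
    return GroundTruth(traits, labels, {}, healthy, noise)


def generate_ratings(E: EmbeddingMatrix, truth: GroundTruth,
                     config: SyntheticConfig) -> RatingTable:
    """Likert ratings from the linear-valuation model.

    ``latent = rating_slope * (item · trait) + rating_offset + N(0, sd_i)``
    on the unit-interval scale, mapped affinely to 1..likert_levels, rounded
    half-up and clipped to the scale bounds.
    """
    if E.dims != truth.healthy_direction.shape[0]:
        raise InvalidInputError("embedding dims do not match ground truth")
    if config.likert_levels < 2:
        raise InvalidRequestError("likert_levels must be at least 2")
    rng = stage_rng(config.seed, "ratings")
    L = config.likert_levels
    frames = []
    sids = sorted(truth.true_traits)
    for sid in sids:
        sd = truth.subject_noise_sd[sid]
        for dim in DIMENSIONS:
            dots = E.vectors @ truth.true_traits[sid][dim]
            latent = config.rating_slope * dots + config.rating_offset
            if sd > 0:
                latent = latent + rng.normal(0.0, sd, size=dots.shape[0])
            mapped = 1.0 + (L - 1) * latent
            ratings = np.clip(np.floor(mapped + 0.5), 1, L).astype(int)
            frames.append(pd.DataFrame({
                "subject_id": sid,
                "item_id": E.item_ids,
                "dimension": dim,
                "rating": ratings,
            }))
    df = pd.concat(frames, ignore_index=True)
    return RatingTable(df, likert_levels=L)


def generate_subject_scores(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Questionnaire scores consistent with the planted group labels.

    Scores are synthetic stand-ins on plausible questionnaire ranges: the
    picky-eating score is centered at 30 (controls) vs 55 (picky group), the
    DSM-style score at 15 vs 40, both with sd 5, so a median split recovers
    the planted groups with high probability.
    """
    rng = stage_rng(config.seed, "subject_scores")
    rows = []
    for sid in sorted(truth.group_labels):
        g = truth.group_labels[sid]
        picky = rng.normal(55.0 if g == "picky_high" else 30.0, 5.0)
        dsm = rng.normal(40.0 if g == "dsm_high" else 15.0, 5.0)
        rows.append([sid, float(picky), float(dsm)])
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def simulate(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic study and write the standard file bundle.

    Emits ``embeddings.csv``, ``ratings.csv``, ``subject_scores.csv`` and
    ``ground_truth.json`` under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    E, cats = generate_embedding_space(config)
    truth = generate_subjects(config)
    truth.item_categories = cats
    R = generate_ratings(E, truth, config)
    scores = generate_subject_scores(truth, config)
    paths = {
        "embeddings": outdir / "embeddings.csv",
        "ratings": outdir / "ratings.csv",
        "subject_scores": outdir / "subject_scores.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_embedding_csv(E, paths["embeddings"])
    write_rating_csv(R, paths["ratings"])
    write_subject_scores(scores, paths["subject_scores"])
    truth.to_json(paths["ground_truth"])
    return paths
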