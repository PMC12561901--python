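"""End-to-end analysis orchestration with validation and manifests.

``run_full_analysis`` composes the individual analyses in their natural
order — population mean-rating models per dimension, per-subject trait
vectors, optional zero-shot evaluation, optional embedding-space comparison,
and group tests — and writes every artifact plus a manifest recording the
configuration hash, seed and input checksums, so any output is regenerable
from the manifest alone.  Metric JSONs contain no timestamps and use sorted
keys, so identical config + seed produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .embeddings import (
    EmbeddingMatrix,
    compare_embedding_spaces,
    distance_matrix,
    read_embedding_csv,
)
from .errors import InvalidRequestError, SchemaError
from .groups import (
    direction_bias_test,
    precision_group_test,
    read_subject_scores,
    split_groups,
)
from .ridge import RidgeConfig
from .traits import (
    DIMENSIONS,
    MEAN_SUBJECT_ID,
    RatingTable,
    fit_all_traits,
    fit_mean_model,
    read_rating_csv,
    write_trait_csv,
)
from .zero_shot import evaluate_zero_shot, read_query_csv, zero_shot_scores

__all__ = ["RunConfig", "ValidationReport", "run_full_analysis", "validate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full analysis run needs, serializable to YAML/JSON."""

    embedding_csv: str
    rating_csv: str
    outdir: str
    scores_csv: str | None = None
    queries_csv: str | None = None
    second_embedding_csv: str | None = None
    dimensions: tuple[str, ...] = DIMENSIONS
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    quantile: float = 0.5
    n_permutations: int = 1000
    seed: int = 0
    likert_levels: int = 8

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ridge = RidgeConfig(**raw.pop("ridge", {}))
        raw.update(overrides)
        if "dimensions" in raw:
            raw["dimensions"] = tuple(raw["dimensions"])
        return cls(ridge=ridge, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dimensions"] = list(self.dimensions)
        return d


@dataclass
class ValidationReport:
    """Report-only input validation: one entry per violation."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"ok": self.ok, "violations": list(self.violations)}


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def validate_inputs(embedding_csv: str | Path, rating_csv: str | Path,
                    scores_csv: str | Path | None = None,
                    likert_levels: int = 8) -> ValidationReport:
    """Schema- and cross-reference-check the input bundle without failing.

    Checks headers, Likert bounds (with row numbers), duplicate records and
    id cross-references between the rating and embedding files; every
    violation found is listed.
    """
    rep = ValidationReport()
    E = None
    try:
        E = read_embedding_csv(embedding_csv)
    except Exception as exc:  # report-only contract
        rep.violations.append(f"embeddings: {exc}")
    try:
        raw = pd.read_csv(rating_csv, dtype={"subject_id": str, "item_id": str})
        expected = ["subject_id", "item_id", "dimension", "rating"]
        if list(raw.columns) != expected:
            rep.violations.append(
                f"ratings: header must be {','.join(expected)}")
            raw = None
    except Exception as exc:
        rep.violations.append(f"ratings: {exc}")
        raw = None
    if raw is not None:
        vals = pd.to_numeric(raw["rating"], errors="coerce")
        for idx in raw.index[vals.isna()]:
            rep.violations.append(f"ratings row {idx + 2}: non-numeric rating")
        bad = raw.index[(vals < 1) | (vals > likert_levels)]
        for idx in bad:
            rep.violations.append(
                f"ratings row {idx + 2}: rating {raw.loc[idx, 'rating']} "
                f"outside 1..{likert_levels}")
        dup = raw.duplicated(subset=["subject_id", "item_id", "dimension"])
        for idx in raw.index[dup]:
            rep.violations.append(
                f"ratings row {idx + 2}: duplicate (subject,item,dimension) record")
        if E is not None:
            missing = sorted(set(raw["item_id"]) - set(E.item_ids))
            for item in missing:
                rep.violations.append(
                    f"cross-reference: item {item!r} rated but absent from embeddings")
    if scores_csv is not None:
        try:
            scores = read_subject_scores(scores_csv)
            if raw is not None:
                missing = sorted(set(raw["subject_id"]) - set(scores["subject_id"]))
                for sid in missing:
                    rep.violations.append(
                        f"cross-reference: subject {sid!r} rated but has no scores")
        except SchemaError as exc:
            rep.violations.append(f"scores: {exc}")
    return rep


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the complete pipeline and write all artifacts plus a manifest.

    Returns the result bundle as a dict (the same content that is written
    to disk).  Raises on schema violations before any output is written.
    """
    report = validate_inputs(cfg.embedding_csv, cfg.rating_csv, cfg.scores_csv,
                             cfg.likert_levels)
    if not report.ok:
        raise SchemaError("input validation failed:\n  " + "\n  ".join(report.violations))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ridge = replace(cfg.ridge, seed=cfg.seed)

    E = read_embedding_csv(cfg.embedding_csv)
    R = read_rating_csv(cfg.rating_csv, likert_levels=cfg.likert_levels)

    outputs: list[str] = []
    bundle: dict = {"config": cfg.to_dict()}

    mean_traits = {}
    for dim in cfg.dimensions:
        trait, cv = fit_mean_model(E, R, dim, ridge)
        mean_traits[dim] = trait
        payload = {"dimension": dim, "model": "mean_rating",
                   "precision_r": trait.precision_r, "cv": cv.to_dict()}
        name = f"mean_model_{dim}.json"
        _write_json(outdir / name, payload)
        outputs.append(name)
        bundle.setdefault("mean_models", {})[dim] = payload

    trait_store = {}
    for dim in cfg.dimensions:
        res = fit_all_traits(E, R, dim, ridge)
        trait_store[dim] = res
        name = f"traits_{dim}.csv"
        write_trait_csv(res.traits, outdir / name)
        outputs.append(name)
        cv_summary = {
            sid: {"mean_r": (None if np.isnan(rep.mean_r) else rep.mean_r),
                  "mean_mse": rep.mean_mse}
            for sid, rep in sorted(res.cv_reports.items())
        }
        payload = {"dimension": dim, "per_subject_cv": cv_summary,
                   "failures": res.failures}
        name = f"individual_cv_{dim}.json"
        _write_json(outdir / name, payload)
        outputs.append(name)
        bundle.setdefault("individual", {})[dim] = payload

    if cfg.queries_csv:
        zs_payload = {}
        for q in read_query_csv(cfg.queries_csv):
            scores_vec = zero_shot_scores(q, E)
            per_dim = {}
            for dim in cfg.dimensions:
                item_ids, y = R.mean_ratings(dim)
                aligned = scores_vec[[E.row_index[i] for i in item_ids]]
                per_dim[dim] = evaluate_zero_shot(aligned, y)
            zs_payload[q.label] = per_dim
        _write_json(outdir / "zero_shot.json", zs_payload)
        outputs.append("zero_shot.json")
        bundle["zero_shot"] = zs_payload

    if cfg.second_embedding_csv:
        E2 = read_embedding_csv(cfg.second_embedding_csv)
        corr = compare_embedding_spaces(distance_matrix(E, "euclidean"),
                                        distance_matrix(E2, "euclidean"))
        payload = {"metric": "euclidean", "distance_matrix_correlation": corr}
        _write_json(outdir / "embedding_comparison.json", payload)
        outputs.append("embedding_comparison.json")
        bundle["embedding_comparison"] = payload

    if cfg.scores_csv:
        scores = read_subject_scores(cfg.scores_csv)
        group_payload = {}
        healthy_ref = mean_traits.get("healthy")
        for field_name in ("picky_score", "dsm_score"):
            groups = split_groups(scores, field_name, cfg.quantile)
            per_field = {}
            for dim in cfg.dimensions:
                res = trait_store[dim]
                test = precision_group_test(res.traits, groups, dim)
                entry = {"precision_test": test.to_dict()}
                if healthy_ref is not None and dim in ("like", "tasty"):
                    lows = [t for t in res.traits if groups.get(t.subject_id) == "low"]
                    highs = [t for t in res.traits if groups.get(t.subject_id) == "high"]
                    gap, p = direction_bias_test(
                        lows, highs, healthy_ref.beta,
                        n_permutations=cfg.n_permutations, seed=cfg.seed)
                    entry["direction_bias"] = {
                        "reference": "mean_healthy_model",
                        "observed_gap": gap, "p_value": p,
                        "n_permutations": cfg.n_permutations, "seed": cfg.seed,
                    }
                per_field[dim] = entry
            group_payload[field_name] = per_field
        _write_json(outdir / "group_tests.json", group_payload)
        outputs.append("group_tests.json")
        bundle["group_tests"] = group_payload

    manifest = {
        "traitspace_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "inputs": {p: _sha256(p) for p in [cfg.embedding_csv, cfg.rating_csv,
                                           cfg.scores_csv, cfg.queries_csv,
                                           cfg.second_embedding_csv] if p},
        "outputs": sorted(outputs),
    }
    _write_json(outdir / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle
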