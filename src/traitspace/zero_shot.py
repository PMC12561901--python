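"""Zero-shot scoring of items against text-derived query vectors.

In a joint vision-language embedding space, a natural-language query such as
"This is a tasty food" has its own vector.  Instead of fitting a rating
model, items can be scored directly by the cosine similarity between the
query vector and each item vector — "asking" the embedding model the rating
question with no training data.  Because a fitted linear readout of
unit-norm embeddings is itself a scaled cosine against the coefficient
direction, zero-shot scoring and model fitting are two routes to the same
geometry; on data generated exactly from a query direction they agree.

Query vectors are supplied as files or by a user plugin provider; nothing
here calls a network service.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingMatrix
from .errors import DegenerateRowError, InvalidInputError, SchemaError
from .ridge import pearson_r
from .traits import cosine_alignment

__all__ = [
    "QueryVector",
    "zero_shot_scores",
    "evaluate_zero_shot",
    "read_query_csv",
    "write_query_csv",
]


@dataclass
class QueryVector:
    """A labeled direction in embedding space, e.g. a text-prompt embedding."""

    label: str
    vector: np.ndarray
    provider_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if self.vector.size == 0 or not np.isfinite(self.vector).all():
            raise InvalidInputError("query vector must be finite and non-empty")
        if np.linalg.norm(self.vector) == 0.0:
            raise InvalidInputError("query vector must be non-zero")


def zero_shot_scores(q: QueryVector, E: EmbeddingMatrix) -> np.ndarray:
    """Cosine similarity between the query and every item, in item order.

    Scores are raw, uncentered cosines in [-1, 1].
    """
    if q.vector.shape[0] != E.dims:
        raise InvalidInputError(
            f"query has {q.vector.shape[0]} dims, embedding has {E.dims}")
    norms = np.linalg.norm(E.vectors, axis=1)
    bad = np.nonzero(norms == 0.0)[0]
    if bad.size:
        raise DegenerateRowError(E.item_ids[int(bad[0])])
    return E.vectors @ q.vector / (norms * np.linalg.norm(q.vector))


def evaluate_zero_shot(scores: np.ndarray, mean_ratings: np.ndarray) -> float:
    """Pearson correlation between zero-shot scores and observed mean ratings.

    Both arguments must already be aligned by item.  The correlation is
    invariant to any positive affine transform of either side, so it does
    not matter whether ratings were rescaled.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    mean_ratings = np.asarray(mean_ratings, dtype=float).ravel()
    if scores.shape != mean_ratings.shape:
        raise InvalidInputError("scores and ratings are not aligned")
    if scores.size < 3:
        raise InvalidInputError("need at least 3 items")
    return pearson_r(scores, mean_ratings)


def consistency_with_fit(q: QueryVector, beta: np.ndarray) -> float:
    """Cosine between a query direction and a fitted coefficient direction."""
    return cosine_alignment(q.vector, beta)


# ---------------------------------------------------------------------------
# file format: label,q0..q{d-1}

_FLOAT_FMT = "%.17g"


def write_query_csv(queries: Sequence[QueryVector], path: str | Path) -> None:
    if not queries:
        raise InvalidInputError("no queries to write")
    d = queries[0].vector.shape[0]
    rows = []
    for q in queries:
        if q.vector.shape[0] != d:
            raise InvalidInputError("queries of mixed dimensionality")
        rows.append([q.label, *q.vector])
    cols = ["label", *[f"q{j}" for j in range(d)]]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_query_csv(path: str | Path, provider_tag: str = "file") -> list[QueryVector]:
    df = pd.read_csv(path, dtype={"label": str})
    if df.columns[0] != "label":
        raise SchemaError("query CSV must start with a label column")
    qcols = list(df.columns[1:])
    if qcols != [f"q{j}" for j in range(len(qcols))]:
        raise SchemaError("query CSV columns must be label,q0,q1,...")
    return [QueryVector(row["label"], row[qcols].to_numpy(float), provider_tag)
            for _, row in df.iterrows()]
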