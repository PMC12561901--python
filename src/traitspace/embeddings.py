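"""Item embedding spaces: construction, I/O, comparison, stimulus selection.

An embedding space assigns every stimulus (a food image, a text label, a
synthetic item) a point in R^d such that distances reflect some notion of
similarity.  Which notion depends on the provider: raw pixels give visual
similarity, label embeddings give semantic similarity, joint vision-language
models give a mixture.  Everything downstream — ridge prediction of ratings,
trait vectors, zero-shot scoring — consumes only the ``EmbeddingMatrix``
produced here, so providers are pluggable: any callable mapping inputs to an
``EmbeddingMatrix`` works.

Two spaces over the same items are compared by correlating their pairwise
distance matrices (the representational-similarity approach): Pearson r over
the strictly upper triangles.  A value near 1 means the spaces induce the
same geometry even if the coordinates differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from ._rng import stage_rng
from .errors import (
    AlignmentError,
    DegenerateRowError,
    InvalidInputError,
    InvalidRequestError,
    UndefinedCorrelationError,
)

__all__ = [
    "EmbeddingMatrix",
    "DistanceMatrix",
    "pixel_embed",
    "distance_matrix",
    "compare_embedding_spaces",
    "select_stimuli_density_weighted",
    "read_embedding_csv",
    "write_embedding_csv",
]

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


@dataclass
class EmbeddingMatrix:
    """Items × dims matrix of embedding vectors with stable item identifiers.

    Parameters
    ----------
    item_ids:
        Ordered, unique string identifiers, one per row.
    vectors:
        2-D float array, one row per item, every entry finite.
    provider_tag:
        Free-form provenance string, e.g. ``"pixel"``, ``"synthetic"`` or
        ``"external:my-vlm"``.
    """

    item_ids: list[str]
    vectors: np.ndarray
    provider_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.item_ids = [str(i) for i in self.item_ids]
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise InvalidInputError("vectors must be a 2-D items × dims array")
        if self.vectors.shape[1] < 1:
            raise InvalidInputError("embedding must have at least one dimension")
        if len(self.item_ids) != self.vectors.shape[0]:
            raise InvalidInputError(
                f"{len(self.item_ids)} item ids but {self.vectors.shape[0]} rows"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise InvalidInputError("duplicate item ids")
        if not np.isfinite(self.vectors).all():
            raise InvalidInputError("non-finite embedding entries")

    @property
    def n_items(self) -> int:
        return self.vectors.shape[0]

    @property
    def dims(self) -> int:
        return self.vectors.shape[1]

    @property
    def row_index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.item_ids)}

    def rows(self, item_ids: Sequence[str]) -> np.ndarray:
        """Rows for ``item_ids`` in the requested order."""
        idx = self.row_index
        try:
            sel = [idx[i] for i in item_ids]
        except KeyError as exc:
            raise AlignmentError(f"unknown item id {exc.args[0]!r}") from None
        return self.vectors[sel]

    def subset(self, item_ids: Sequence[str]) -> "EmbeddingMatrix":
        return EmbeddingMatrix(list(item_ids), self.rows(item_ids), self.provider_tag)


@dataclass
class DistanceMatrix:
    """Symmetric item × item distance matrix with zero diagonal."""

    item_ids: list[str]
    D: np.ndarray
    metric_tag: str = "euclidean"

    def __post_init__(self) -> None:
        self.item_ids = [str(i) for i in self.item_ids]
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.item_ids)
        if self.D.shape != (n, n):
            raise InvalidInputError("distance matrix shape does not match item count")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise InvalidInputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise InvalidInputError("distance matrix diagonal is not zero")
        if (self.D < -1e-12).any():
            raise InvalidInputError("negative distances")


def pixel_embed(image: np.ndarray, target_size: tuple[int, int] | None = (224, 224)) -> np.ndarray:
    """Flatten a (resized) intensity image into a pixel-baseline embedding vector.

    The pixel baseline represents an image by its raw intensities after
    resizing to a fixed grid (default 224×224, the standard vision-model
    input size), so Euclidean distance between two embeddings is pixel-level
    visual distance.  Resizing is bilinear and deterministic; channels are
    preserved and the array is flattened row-major.

    Pass ``target_size=None`` to skip resizing.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if not np.issubdtype(arr.dtype, np.number):
        raise InvalidInputError("non-numeric pixel values")
    arr = arr.astype(float)
    if arr.ndim not in (2, 3):
        raise InvalidInputError("image must be 2-D (grayscale) or 3-D (channels last)")
    if not np.isfinite(arr).all():
        raise InvalidInputError("non-finite pixel values")
    if target_size is not None:
        th, tw = int(target_size[0]), int(target_size[1])
        if th < 1 or tw < 1:
            raise InvalidInputError("target_size must be positive")
        from skimage.transform import resize  # local import: heavy module

        out_shape = (th, tw) + arr.shape[2:]
        arr = resize(arr, out_shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return arr.ravel(order="C")


def distance_matrix(E: EmbeddingMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between all items of ``E``.

    ``metric`` is ``"euclidean"`` or ``"cosine_distance"``
    (1 − cosine similarity, so identical directions are at distance 0).
    """
    if E.n_items < 2:
        raise InvalidRequestError("need at least 2 items for a distance matrix")
    if metric == "euclidean":
        D = squareform(pdist(E.vectors, metric="euclidean"))
    elif metric == "cosine_distance":
        norms = np.linalg.norm(E.vectors, axis=1)
        bad = np.nonzero(norms == 0.0)[0]
        if bad.size:
            raise DegenerateRowError(E.item_ids[int(bad[0])])
        D = squareform(pdist(E.vectors, metric="cosine"))
    else:
        raise InvalidRequestError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return DistanceMatrix(list(E.item_ids), (D + D.T) / 2.0, metric_tag=metric)


def compare_embedding_spaces(D1: DistanceMatrix, D2: DistanceMatrix) -> float:
    """Pearson correlation of two distance matrices over their upper triangles.

    The matrices are aligned by item id first (same set required, order may
    differ).  The strictly upper triangle is used so symmetric entries are
    not double-counted and the zero diagonal does not bias the correlation.
    """
    if set(D1.item_ids) != set(D2.item_ids):
        raise AlignmentError("distance matrices cover different item sets")
    n = len(D1.item_ids)
    if n < 3:
        raise InvalidRequestError("need at least 3 items to correlate distances")
    if D1.item_ids != D2.item_ids:
        idx2 = {i: k for k, i in enumerate(D2.item_ids)}
        perm = [idx2[i] for i in D1.item_ids]
        d2 = D2.D[np.ix_(perm, perm)]
    else:
        d2 = D2.D
    iu = np.triu_indices(n, k=1)
    a, b = D1.D[iu], d2[iu]
    tol_a = 1e-12 * max(1.0, float(np.abs(a).max()))
    tol_b = 1e-12 * max(1.0, float(np.abs(b).max()))
    if np.ptp(a) <= tol_a or np.ptp(b) <= tol_b:
        raise UndefinedCorrelationError("a distance triangle has zero variance")
    return float(pearsonr(a, b)[0])


def select_stimuli_density_weighted(
    E: EmbeddingMatrix,
    n_select: int,
    k_neighbors: int = 10,
    seed: int = 0,
) -> list[str]:
    """Sample a stimulus subset, over-weighting sparse regions of the space.

    Rating every item in a large stimulus set is costly; sampling uniformly
    over-represents dense clusters of near-duplicates.  This selector uses
    the distance to the k-th nearest neighbor as an inverse-density proxy and
    samples ``n_select`` items without replacement with probability
    proportional to that distance, so isolated items are favoured.  This is
    a simple k-NN density stand-in, not a canonical formula.

    Deterministic for a fixed ``seed``.
    """
    n = E.n_items
    if n_select > n:
        raise InvalidRequestError(f"cannot select {n_select} of {n} items")
    if n_select < 1:
        raise InvalidRequestError("n_select must be positive")
    if k_neighbors >= n or k_neighbors < 1:
        raise InvalidRequestError("k_neighbors must be in [1, n_items)")
    if n_select == n:
        return list(E.item_ids)
    tree = cKDTree(E.vectors)
    dist, _ = tree.query(E.vectors, k=k_neighbors + 1)
    w = dist[:, k_neighbors]
    if w.sum() == 0.0:  # all items coincide: fall back to uniform weights
        w = np.ones(n)
    rng = stage_rng(seed, "density_weighted_selection")
    # Efraimidis-Spirakis keys: taking the n_select largest realizes exact
    # sequential weighted sampling without replacement.
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        keys = np.log(u) / np.where(w > 0, w, np.nan)
    keys = np.where(w > 0, keys, -np.inf)
    chosen = np.sort(np.argpartition(keys, -n_select)[-n_select:])
    return [E.item_ids[int(i)] for i in chosen]


def pixel_embedding_matrix(images: Mapping[str, np.ndarray],
                           target_size: tuple[int, int] | None = (224, 224),
                           ) -> EmbeddingMatrix:
    """Shipped "pixel" provider: embed a set of images by resized raw pixels.

    ``images`` maps item ids to intensity arrays; every image is resized to
    ``target_size`` (so all vectors share one dimensionality) and flattened.
    Any callable with this signature returning an :class:`EmbeddingMatrix`
    can serve as an embedding provider — external vision-language models
    plug in the same way.
    """
    if not images:
        raise InvalidInputError("no images supplied")
    ids = list(images)
    vectors = np.stack([pixel_embed(images[i], target_size) for i in ids])
    return EmbeddingMatrix(ids, vectors, provider_tag="pixel")


# ---------------------------------------------------------------------------
# file formats


def write_embedding_csv(E: EmbeddingMatrix, path: str | Path) -> None:
    """Write ``item_id,e0,e1,...`` CSV; values round-trip losslessly."""
    cols = [f"e{j}" for j in range(E.dims)]
    df = pd.DataFrame(E.vectors, columns=cols)
    df.insert(0, "item_id", E.item_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_embedding_csv(path: str | Path, provider_tag: str | None = None) -> EmbeddingMatrix:
    df = pd.read_csv(path, dtype={"item_id": str})
    if df.columns[0] != "item_id":
        raise InvalidInputError("embedding CSV must start with an item_id column")
    expected = [f"e{j}" for j in range(df.shape[1] - 1)]
    if list(df.columns[1:]) != expected:
        raise InvalidInputError("embedding CSV columns must be item_id,e0,e1,...")
    tag = provider_tag if provider_tag is not None else f"file:{Path(path).name}"
    return EmbeddingMatrix(df["item_id"].tolist(), df[expected].to_numpy(float), tag)


def write_embedding_npy(E: EmbeddingMatrix, matrix_path: str | Path,
                        ids_path: str | Path) -> None:
    """Binary alternative for large dims: ``.npy`` matrix + newline-separated id list."""
    np.save(matrix_path, E.vectors)
    Path(ids_path).write_text("\n".join(E.item_ids) + "\n")


def read_embedding_npy(matrix_path: str | Path, ids_path: str | Path,
                       provider_tag: str = "binary") -> EmbeddingMatrix:
    ids = Path(ids_path).read_text().splitlines()
    return EmbeddingMatrix(ids, np.load(matrix_path), provider_tag)
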