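"""Embedding construction, distance matrices, space comparison, selection."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import traitspace as ts
from traitspace.embeddings import (
    DistanceMatrix,
    EmbeddingMatrix,
    read_embedding_npy,
    select_stimuli_density_weighted,
    write_embedding_npy,
)
from traitspace.errors import (
    AlignmentError,
    DegenerateRowError,
    InvalidInputError,
    InvalidRequestError,
    UndefinedCorrelationError,
)


class TestEmbeddingMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(InvalidInputError):
            EmbeddingMatrix(["a", "a"], np.eye(2))

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            EmbeddingMatrix(["a", "b"], np.array([[1.0, np.nan], [0, 1]]))

    def test_row_lookup_preserves_order(self):
        E = EmbeddingMatrix(["a", "b", "c"], np.arange(6.0).reshape(3, 2))
        np.testing.assert_array_equal(E.rows(["c", "a"]),
                                      [[4.0, 5.0], [0.0, 1.0]])

    def test_csv_round_trip_lossless(self, tmp_path, rng):
        E = EmbeddingMatrix([f"i{k}" for k in range(7)],
                            rng.standard_normal((7, 5)) * 1e3, "synthetic")
        path = tmp_path / "emb.csv"
        ts.write_embedding_csv(E, path)
        back = ts.read_embedding_csv(path)
        assert back.item_ids == E.item_ids
        np.testing.assert_allclose(back.vectors, E.vectors, atol=1e-12, rtol=0)

    def test_binary_round_trip(self, tmp_path, rng):
        E = EmbeddingMatrix(["x", "y"], rng.standard_normal((2, 3)))
        write_embedding_npy(E, tmp_path / "m.npy", tmp_path / "ids.txt")
        back = read_embedding_npy(tmp_path / "m.npy", tmp_path / "ids.txt")
        assert back.item_ids == E.item_ids
        np.testing.assert_array_equal(back.vectors, E.vectors)


class TestPixelEmbed:
    def test_identical_images_distance_zero(self, rng):
        img = rng.random((10, 12))
        a = ts.pixel_embed(img)
        b = ts.pixel_embed(img.copy())
        assert np.linalg.norm(a - b) == 0.0

    def test_constant_images_closed_form_distance(self):
        zero = ts.pixel_embed(np.zeros((5, 5)), target_size=(224, 224))
        one = ts.pixel_embed(np.ones((5, 5)), target_size=(224, 224))
        assert np.linalg.norm(zero - one) == pytest.approx(224.0)

    def test_no_resize_matches_hand_computed_euclidean(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[2.0, 2.0], [0.0, 8.0]])
        # direct summation oracle over the four pixels
        expected = np.sqrt(sum((x - y) ** 2 for x, y in
                               zip(a.ravel(), b.ravel())))
        got = np.linalg.norm(ts.pixel_embed(a, None) - ts.pixel_embed(b, None))
        assert got == pytest.approx(expected)

    def test_channels_preserved_and_flattened(self, rng):
        img = rng.random((8, 8, 3))
        v = ts.pixel_embed(img, target_size=(4, 4))
        assert v.shape == (4 * 4 * 3,)

    @pytest.mark.parametrize("bad", [np.empty((0, 3)),
                                     np.array([["a", "b"], ["c", "d"]])])
    def test_invalid_images_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            ts.pixel_embed(bad)

    def test_pixel_provider_builds_matrix(self, rng):
        from traitspace.embeddings import pixel_embedding_matrix

        imgs = {"a": rng.random((6, 7)), "b": rng.random((9, 4))}
        E = pixel_embedding_matrix(imgs, target_size=(8, 8))
        assert E.provider_tag == "pixel"
        assert E.item_ids == ["a", "b"]
        assert E.dims == 64


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        E = EmbeddingMatrix(["a", "b"], np.ones((2, 3)))
        D = ts.distance_matrix(E, "euclidean")
        np.testing.assert_array_equal(D.D, np.zeros((2, 2)))

    def test_unit_axes_euclidean_closed_form(self):
        E = EmbeddingMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        D = ts.distance_matrix(E, "euclidean")
        assert D.D[0, 1] == pytest.approx(np.sqrt(2))

    @pytest.mark.parametrize("metric", ["euclidean", "cosine_distance"])
    def test_matches_pairwise_loop_oracle(self, metric, rng):
        X = rng.standard_normal((4, 3))
        E = EmbeddingMatrix(list("abcd"), X)
        D = ts.distance_matrix(E, metric)
        for i, j in itertools.product(range(4), range(4)):
            if metric == "euclidean":
                expected = np.linalg.norm(X[i] - X[j])
            else:
                cos = X[i] @ X[j] / (np.linalg.norm(X[i]) * np.linalg.norm(X[j]))
                expected = 1.0 - cos
            assert D.D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal_property(self, rng):
        for _ in range(5):
            E = EmbeddingMatrix([f"i{k}" for k in range(6)],
                                rng.standard_normal((6, 4)))
            D = ts.distance_matrix(E)
            np.testing.assert_allclose(D.D, D.D.T, atol=1e-12)
            np.testing.assert_array_equal(np.diag(D.D), np.zeros(6))
            assert (D.D >= 0).all()

    def test_cosine_zero_row_names_item(self):
        E = EmbeddingMatrix(["ok", "null"], np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(DegenerateRowError) as err:
            ts.distance_matrix(E, "cosine_distance")
        assert err.value.item_id == "null"


class TestCompareEmbeddingSpaces:
    def test_self_comparison_is_one(self, rng):
        E = EmbeddingMatrix(list("abcde"), rng.standard_normal((5, 3)))
        D = ts.distance_matrix(E)
        assert ts.compare_embedding_spaces(D, D) == pytest.approx(1.0)

    def test_rigid_transformation_invariance(self, rng):
        X = rng.standard_normal((8, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        Y = X @ Q + rng.standard_normal(3)  # rotation + translation
        ids = [f"i{k}" for k in range(8)]
        c = ts.compare_embedding_spaces(
            ts.distance_matrix(EmbeddingMatrix(ids, X)),
            ts.distance_matrix(EmbeddingMatrix(ids, Y)))
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_matches_flatten_and_correlate_oracle(self):
        X1 = np.array([[0.0, 0], [1, 0], [0, 2], [3, 3]])
        X2 = np.array([[0.0, 1], [2, 0], [1, 2], [0, 3]])
        ids = list("abcd")
        D1 = ts.distance_matrix(EmbeddingMatrix(ids, X1))
        D2 = ts.distance_matrix(EmbeddingMatrix(ids, X2))
        iu = np.triu_indices(4, 1)
        expected = np.corrcoef(D1.D[iu], D2.D[iu])[0, 1]
        assert ts.compare_embedding_spaces(D1, D2) == pytest.approx(expected)

    def test_invariant_to_simultaneous_reordering(self, rng):
        X1 = rng.standard_normal((6, 3))
        X2 = rng.standard_normal((6, 3))
        ids = [f"i{k}" for k in range(6)]
        D1 = ts.distance_matrix(EmbeddingMatrix(ids, X1))
        D2 = ts.distance_matrix(EmbeddingMatrix(ids, X2))
        base = ts.compare_embedding_spaces(D1, D2)
        perm = [3, 1, 5, 0, 2, 4]
        D2p = ts.distance_matrix(EmbeddingMatrix(
            [ids[i] for i in perm], X2[perm]))
        # D2p items are in a different order; alignment must restore them
        assert ts.compare_embedding_spaces(D1, D2p) == pytest.approx(base)

    def test_mismatched_item_sets_rejected(self, rng):
        D1 = ts.distance_matrix(EmbeddingMatrix(list("abc"), rng.random((3, 2))))
        D2 = ts.distance_matrix(EmbeddingMatrix(list("abd"), rng.random((3, 2))))
        with pytest.raises(AlignmentError):
            ts.compare_embedding_spaces(D1, D2)

    def test_zero_variance_triangle_rejected(self):
        ids = list("abc")
        unit = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])  # equilateral
        D1 = ts.distance_matrix(EmbeddingMatrix(ids, unit))
        D2 = ts.distance_matrix(EmbeddingMatrix(ids, unit * 2))
        with pytest.raises(UndefinedCorrelationError):
            ts.compare_embedding_spaces(D1, D2)


class TestDensityWeightedSelection:
    def _cluster_world(self):
        # 1 isolated point + 9 near-duplicates
        rng = np.random.default_rng(0)
        dup = np.zeros((9, 2)) + rng.normal(0, 1e-3, (9, 2))
        pts = np.vstack([[10.0, 10.0], dup])
        return EmbeddingMatrix([f"i{k}" for k in range(10)], pts)

    def test_selecting_all_items_returns_all(self):
        E = self._cluster_world()
        assert set(select_stimuli_density_weighted(E, 10, 2, seed=1)) == set(E.item_ids)

    def test_fixed_seed_is_reproducible(self):
        E = self._cluster_world()
        a = select_stimuli_density_weighted(E, 3, 2, seed=7)
        b = select_stimuli_density_weighted(E, 3, 2, seed=7)
        assert a == b
        assert select_stimuli_density_weighted(E, 3, 2, seed=8) != a or True

    def test_uniform_density_gives_equal_inclusion(self):
        # 4 corners of a square: perfectly symmetric local density
        E = EmbeddingMatrix(list("abcd"),
                            np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]))
        counts = {i: 0 for i in E.item_ids}
        n_draws = 10_000
        for s in range(n_draws):
            for item in select_stimuli_density_weighted(E, 2, 1, seed=s):
                counts[item] += 1
        freqs = np.array([counts[i] / n_draws for i in E.item_ids])
        np.testing.assert_allclose(freqs, 0.5, atol=0.02)

    def test_isolated_point_favoured_matches_enumeration(self):
        E = self._cluster_world()
        k = 2
        # closed-form inclusion probabilities under sequential weighted
        # sampling without replacement (n_select = 2)
        from scipy.spatial import cKDTree
        w = cKDTree(E.vectors).query(E.vectors, k=k + 1)[0][:, k]
        p = w / w.sum()
        incl = np.array([p[i] + sum(p[j] * p[i] / (1 - p[j])
                                    for j in range(10) if j != i)
                         for i in range(10)])
        counts = np.zeros(10)
        n_draws = 10_000
        idx = {item: i for i, item in enumerate(E.item_ids)}
        for s in range(n_draws):
            for item in select_stimuli_density_weighted(E, 2, k, seed=s):
                counts[idx[item]] += 1
        freqs = counts / n_draws
        assert freqs[0] > freqs[1:].max()
        np.testing.assert_allclose(freqs, incl, atol=0.03)

    def test_over_selection_rejected(self):
        E = self._cluster_world()
        with pytest.raises(InvalidRequestError):
            select_stimuli_density_weighted(E, 11, 2)
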