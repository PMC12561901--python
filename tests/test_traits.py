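"""Rating tables, trait-vector fitting, precision statistics."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import traitspace as ts
from traitspace.errors import (
    InvalidRequestError,
    SchemaError,
    UndefinedAlignmentError,
)
from traitspace.ridge import RidgeConfig
from traitspace.synthetic import SyntheticConfig, generate_embedding_space

from conftest import make_rating_table


@pytest.fixture(scope="module")
def unit_items():
    cfg = SyntheticConfig(n_items=400, n_subjects=1, dims=32, n_categories=8, seed=9)
    E, _ = generate_embedding_space(cfg)
    return E


class TestRatingTable:
    def _frame(self, **over):
        base = dict(subject_id=["s1", "s1"], item_id=["a", "b"],
                    dimension=["like", "like"], rating=[3, 8])
        base.update(over)
        return pd.DataFrame(base)

    def test_valid_table_accepted(self):
        R = ts.RatingTable(self._frame())
        assert len(R) == 2
        assert R.subject_ids == ["s1"]

    def test_out_of_bounds_rating_rejected(self):
        with pytest.raises(SchemaError):
            ts.RatingTable(self._frame(rating=[0, 5]))
        with pytest.raises(SchemaError):
            ts.RatingTable(self._frame(rating=[9, 5]))

    def test_duplicate_record_rejected(self):
        with pytest.raises(SchemaError):
            ts.RatingTable(self._frame(item_id=["a", "a"]))

    def test_unknown_dimension_rejected(self):
        with pytest.raises(SchemaError):
            ts.RatingTable(self._frame(dimension=["like", "spicy"]))

    def test_mean_ratings_across_subjects(self):
        df = pd.DataFrame({
            "subject_id": ["s1", "s2", "s1"],
            "item_id": ["a", "a", "b"],
            "dimension": ["like"] * 3,
            "rating": [2, 6, 8],
        })
        items, means = ts.RatingTable(df).mean_ratings("like")
        assert items == ["a", "b"]
        np.testing.assert_allclose(means, [4.0, 8.0])

    def test_rating_csv_round_trip(self, tmp_path, small_world):
        _, _, _, R = small_world
        path = tmp_path / "ratings.csv"
        from traitspace.traits import write_rating_csv

        write_rating_csv(R, path)
        back = ts.read_rating_csv(path)
        pd.testing.assert_frame_equal(back.df, R.df)


class TestCosineAlignment:
    def test_self_alignment_is_one(self, rng):
        v = rng.standard_normal(5)
        assert ts.cosine_alignment(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_are_zero(self):
        assert ts.cosine_alignment([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_forty_five_degrees(self):
        assert ts.cosine_alignment([1.0, 1.0], [1.0, 0.0]) == pytest.approx(
            math.sqrt(2) / 2, abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedAlignmentError):
            ts.cosine_alignment([0.0, 0.0], [1.0, 0.0])


class TestFitMeanModel:
    def test_default_config_matches_study_settings(self, default_config):
        assert default_config.lam == 1.0
        assert default_config.n_folds == 5

    def test_constant_ratings_flag_undefined_precision(self, unit_items):
        df = pd.DataFrame({
            "subject_id": "s1", "item_id": unit_items.item_ids,
            "dimension": "like", "rating": 5})
        R = ts.RatingTable(df)
        trait, rep = ts.fit_mean_model(unit_items, R, "like")
        assert not trait.precision_defined
        assert rep.undefined_r_folds == list(range(5))

    def test_shared_trait_low_noise_high_cv_r(self, unit_items, rng):
        # many subjects share one trait; averaging smooths the Likert
        # discretization, so the mean-rating model predicts well
        beta = rng.standard_normal(32)
        beta /= np.linalg.norm(beta)
        frames = [make_rating_table(unit_items, beta, subject_id=f"s{k}",
                                    noise_sd=0.1, seed=k).df
                  for k in range(30)]
        R = ts.RatingTable(pd.concat(frames, ignore_index=True))
        _, rep = ts.fit_mean_model(unit_items, R, "like",
                                   RidgeConfig(lam=0.01))
        assert rep.mean_r >= 0.95

    def test_absent_dimension_rejected(self, unit_items, rng):
        R = make_rating_table(unit_items, rng.standard_normal(32))
        with pytest.raises(InvalidRequestError):
            ts.fit_mean_model(unit_items, R, "healthy")


class TestFitTraitVector:
    def test_noiseless_recovery_fine_scale(self, unit_items, rng):
        # noiseless ratings on a fine integer scale: quantization negligible
        q = rng.standard_normal(32)
        q /= np.linalg.norm(q)
        R = make_rating_table(unit_items, q, noise_sd=0.0, likert_levels=1000)
        t = ts.fit_trait_vector(unit_items, R, "s0", "like", RidgeConfig(lam=1e-9))
        assert t.precision_r >= 0.999
        assert ts.cosine_alignment(t.beta, q) >= 0.99

    def test_noiseless_recovery_coarse_likert(self, unit_items, rng):
        # 8-level quantization alone caps recovery slightly below the
        # fine-scale case
        q = rng.standard_normal(32)
        q /= np.linalg.norm(q)
        R = make_rating_table(unit_items, q, noise_sd=0.0, likert_levels=8)
        t = ts.fit_trait_vector(unit_items, R, "s0", "like", RidgeConfig(lam=1e-9))
        assert ts.cosine_alignment(t.beta, q) >= 0.95

    def test_pure_noise_matches_permutation_oracle(self, rng):
        # ratings independent of embeddings: in-sample precision reflects
        # overfitting only, and must match the permutation-null level
        cfg = SyntheticConfig(n_items=50, n_subjects=1, dims=8, n_categories=4,
                              seed=3)
        E, _ = generate_embedding_space(cfg)
        ratings = rng.integers(1, 9, size=50)
        df = pd.DataFrame({"subject_id": "s0", "item_id": E.item_ids,
                           "dimension": "like", "rating": ratings})
        R = ts.RatingTable(df)
        t = ts.fit_trait_vector(E, R, "s0", "like", RidgeConfig(lam=1.0))
        null = []
        y01 = (np.asarray(ratings, float) - 1) / 7.0
        for _ in range(200):
            perm = rng.permutation(50)
            beta, b0 = ts.ridge_fit(E.vectors, y01[perm], RidgeConfig(lam=1.0))
            null.append(ts.pearson_r(E.vectors @ beta + b0, y01[perm]))
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= t.precision_r <= hi

    def test_constant_ratings_flagged(self, unit_items):
        df = pd.DataFrame({"subject_id": "s0", "item_id": unit_items.item_ids,
                           "dimension": "like", "rating": 5})
        t = ts.fit_trait_vector(unit_items, ts.RatingTable(df), "s0", "like")
        assert not t.precision_defined

    def test_unknown_subject_rejected(self, unit_items, rng):
        R = make_rating_table(unit_items, rng.standard_normal(32))
        with pytest.raises(InvalidRequestError):
            ts.fit_trait_vector(unit_items, R, "ghost", "like")

    def test_precision_exceeds_held_out_cv_r(self, small_world):
        # in-sample optimism: full-data precision >= mean held-out r
        _, E, _, R = small_world
        res = ts.fit_all_traits(E, R, "like", RidgeConfig(lam=1.0))
        diffs = [t.precision_r - res.cv_reports[t.subject_id].mean_r
                 for t in res.traits if t.precision_defined]
        assert np.median(diffs) > 0
        assert np.mean(np.array(diffs) > -0.02) > 0.9


class TestFitAllTraits:
    def test_identical_subjects_identical_traits(self, unit_items, rng):
        beta = rng.standard_normal(32)
        frames = []
        for sid in ("s1", "s2"):
            t = make_rating_table(unit_items, beta, subject_id=sid)
            frames.append(t.df)
        R = ts.RatingTable(pd.concat(frames, ignore_index=True))
        res = ts.fit_all_traits(unit_items, R, "like")
        assert len(res.traits) == 2
        np.testing.assert_allclose(res.traits[0].beta, res.traits[1].beta)

    def test_dimension_nobody_rated_returns_empty(self, unit_items, rng):
        R = make_rating_table(unit_items, rng.standard_normal(32),
                              dimension="tasty")
        res = ts.fit_all_traits(unit_items, R, "healthy")
        assert res.traits == []
        assert res.failures == {}

    def test_subjects_sorted_deterministically(self, small_world):
        _, E, _, R = small_world
        res = ts.fit_all_traits(E, R, "healthy", RidgeConfig(lam=1.0))
        sids = [t.subject_id for t in res.traits]
        assert sids == sorted(sids)


class TestScalingIdentity:
    def test_prediction_equals_scaled_cosine(self, unit_items, rng):
        # with unit-norm rows and zero intercept the linear readout IS a
        # scaled cosine against the coefficient direction
        beta = rng.standard_normal(32)
        pred = ts.predict(unit_items.vectors, beta, 0.0)
        cosines = np.array([ts.cosine_alignment(beta, row)
                            for row in unit_items.vectors])
        np.testing.assert_allclose(pred, np.linalg.norm(beta) * cosines,
                                   atol=1e-10)


class TestTraitCSV:
    def test_round_trip_lossless(self, tmp_path, small_world):
        _, E, _, R = small_world
        res = ts.fit_all_traits(E, R, "like", RidgeConfig(lam=1.0))
        path = tmp_path / "traits.csv"
        ts.write_trait_csv(res.traits, path)
        back = ts.read_trait_csv(path)
        assert len(back) == len(res.traits)
        for a, b in zip(res.traits, back):
            assert a.subject_id == b.subject_id
            np.testing.assert_allclose(a.beta, b.beta, atol=1e-12)
            assert a.precision_r == pytest.approx(b.precision_r, abs=1e-12)
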