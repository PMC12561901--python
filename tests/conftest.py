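"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import traitspace as ts
from traitspace.ridge import RidgeConfig


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study: 120 items, 24 subjects, 16 dims."""
    cfg = ts.SyntheticConfig(n_items=120, n_subjects=24, dims=16, n_categories=4,
                             noise_sd=0.2, picky_fraction=0.25, dsm_fraction=0.25,
                             seed=42)
    E, cats = ts.generate_embedding_space(cfg)
    truth = ts.generate_subjects(cfg)
    truth.item_categories = cats
    R = ts.generate_ratings(E, truth, cfg)
    return cfg, E, truth, R


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_rating_table(E, beta, subject_id="s0", dimension="like",
                      noise_sd=0.0, likert_levels=8, seed=0, intercept=0.5,
                      slope=0.5):
    """Ratings generated directly from a known coefficient direction."""
    rng = np.random.default_rng(seed)
    latent = slope * (E.vectors @ beta) + intercept
    if noise_sd > 0:
        latent = latent + rng.normal(0, noise_sd, size=len(latent))
    mapped = 1.0 + (likert_levels - 1) * latent
    ratings = np.clip(np.floor(mapped + 0.5), 1, likert_levels).astype(int)
    df = pd.DataFrame({
        "subject_id": subject_id,
        "item_id": E.item_ids,
        "dimension": dimension,
        "rating": ratings,
    })
    return ts.RatingTable(df, likert_levels=likert_levels)


@pytest.fixture()
def default_config():
    return RidgeConfig()
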