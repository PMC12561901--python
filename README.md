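# traitspace

Embedding-space preference modeling for item-rating studies.

## The problem

Rating studies in behavioral phenotyping and computational psychiatry ask
many subjects to rate many stimuli — here, food images rated 1–8 on *like*,
*tasty* and *healthy* — and then need to (a) predict ratings for unseen
items and (b) summarize each subject's preferences in a form that can be
related to clinical questionnaire scores.  When each item has an embedding
vector (from a vision-language model, raw pixels, or any other provider),
both problems become linear geometry in the embedding space.

`traitspace` implements that analysis as a tested, reusable library:

- **Mean-rating model** — ridge regression of per-item mean ratings on
  embeddings, `min_β ‖y − Xβ‖² + λ‖β‖²` (default λ = 1.0, 5-fold CV,
  MSE + Pearson r metrics, one-standard-error λ selection).
- **Trait vectors** — the ridge coefficient vector `β_i` fitted on *all* of
  subject *i*'s ratings is their preference direction in embedding space;
  the correlation `r_i` between full-data predictions and observations is
  the subject's precision.  With unit-norm embeddings, `Xβ` equals
  `‖β‖ · cos(β, x_j)` per item, so a trait vector reads as "the item the
  subject is asking for".
- **Zero-shot scoring** — score items by cosine similarity to a text-query
  direction (e.g. the embedding of "This is a tasty food"), no fitting.
- **Embedding-space comparison** — Pearson correlation of pairwise distance
  matrices (upper triangles) between two spaces over the same items; a
  pixel baseline embedder (resize → flatten) is included.
- **Group analysis** — median (or any quantile) splits on picky-eating and
  DSM-style questionnaire scores; Mann–Whitney U (exact enumeration with
  midrank ties for small samples) on precision values; seeded permutation
  test for trait-direction bias relative to a healthy reference direction.
- **Synthetic testbed** — a generator producing clustered unit-sphere
  embeddings, per-subject trait vectors with planted group effects (picky
  rotation away from the healthy axis, inflated high-DSM noise), and Likert
  ratings — with ground truth exposed so every estimator is tested against
  truth.

## Worked example

```python
import traitspace as ts
from traitspace.ridge import RidgeConfig

cfg = ts.SyntheticConfig(n_items=300, n_subjects=40, dims=32, n_categories=8, seed=1)
E, _ = ts.generate_embedding_space(cfg)
truth = ts.generate_subjects(cfg)
R = ts.generate_ratings(E, truth, cfg)

for dim in ts.DIMENSIONS:
    trait, cv = ts.fit_mean_model(E, R, dim, RidgeConfig(lam=1.0))
    print(f"{dim:8s}  CV r = {cv.mean_r:.3f} +/- {cv.sd_r:.3f}   "
          f"CV MSE = {cv.mean_mse:.4f} (unit-interval scale)")
```

prints

```
like      CV r = 0.711 +/- 0.050   CV MSE = 0.0023 (unit-interval scale)
tasty     CV r = 0.658 +/- 0.048   CV MSE = 0.0024 (unit-interval scale)
healthy   CV r = 0.669 +/- 0.040   CV MSE = 0.0027 (unit-interval scale)
```

CV r is the Pearson correlation between held-out mean ratings and the
model's predictions: how well the embedding geometry explains what the
average rater likes.  MSE is reported on the fitted scale (ratings are
mapped from 1–8 onto [0, 1] by default before fitting).

The `examples/` directory has one short script per capability:
mean-rating modeling, individual trait extraction and recovery, zero-shot
scoring, embedding-space comparison, group-difference testing, and
stimulus selection / λ selection.

A thin CLI mirrors the library:

```bash
traitspace simulate --out sim --seed 1 --n-items 200 --n-subjects 30 --dims 16
traitspace run-all --embeddings sim/embeddings.csv --ratings sim/ratings.csv \
    --scores sim/subject_scores.csv --out results --seed 1
```

`run-all` writes per-dimension model metrics, trait CSVs, group-test JSONs
and a manifest with config hash, seed and input checksums; re-running with
the same config and seed reproduces every file byte for byte.

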