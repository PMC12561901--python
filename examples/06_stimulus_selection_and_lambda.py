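"""Density-weighted stimulus selection and regularization-path selection.

Two design utilities: picking a stimulus subset that over-weights sparse
regions of the embedding space, and choosing the ridge penalty by
cross-validation with the one-standard-error rule.
"""

import numpy as np

import traitspace as ts
from traitspace.ridge import RidgeConfig

cfg = ts.SyntheticConfig(n_items=200, n_subjects=1, dims=16, n_categories=5,
                         cluster_concentration=8.0, seed=6)
E, cats = ts.generate_embedding_space(cfg)

subset = ts.select_stimuli_density_weighted(E, n_select=40, k_neighbors=5, seed=6)
picked_cats = [cats[i] for i in subset]
print(f"selected {len(subset)} of {E.n_items} items; "
      f"categories represented: {sorted(set(picked_cats))}")

# lambda selection on mean ratings of a synthetic study
truth = ts.generate_subjects(cfg)
rng = np.random.default_rng(6)
y = E.vectors @ truth.true_traits[list(truth.true_traits)[0]]["like"]
y = y + rng.normal(0, 0.2, size=len(y))
grid = list(np.logspace(-3, 2, 8))
lam_min, lam_1se, path = ts.lambda_sweep_one_se(
    E.vectors, y, grid, RidgeConfig(rating_rescale="none"))
print(f"lambda minimizing CV MSE : {lam_min:.4g}")
print(f"one-standard-error choice: {lam_1se:.4g} "
      f"(largest lambda within 1 SE of the minimum)")

# The one-SE choice trades a statistically negligible amount of held-out
# error for a more strongly regularized, more stable coefficient vector.
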