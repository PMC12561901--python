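"""Compare two embedding spaces of the same items by distance correlation.

Two providers (here: the synthetic space and a pixel-style baseline built
from random projections of it) induce different geometries; correlating
their pairwise distance matrices quantifies how similar those geometries
are.  A rigid transformation of the same space correlates perfectly.
"""

import numpy as np

import traitspace as ts

cfg = ts.SyntheticConfig(n_items=150, n_subjects=1, dims=32, n_categories=6,
                         seed=4)
E, _ = ts.generate_embedding_space(cfg)
rng = np.random.default_rng(4)

# same geometry, rotated and shifted
Q, _ = np.linalg.qr(rng.standard_normal((32, 32)))
E_rot = ts.EmbeddingMatrix(E.item_ids, E.vectors @ Q + 0.5, "synthetic-rotated")

# unrelated space over the same items
E_noise = ts.EmbeddingMatrix(E.item_ids, rng.standard_normal((150, 32)),
                             "unrelated")

D = ts.distance_matrix(E)
for other, label in [(E_rot, "rigidly transformed copy"),
                     (E_noise, "unrelated random space")]:
    c = ts.compare_embedding_spaces(D, ts.distance_matrix(other))
    print(f"{label:28s}: distance-matrix correlation r = {c:.3f}")

# Near 1.0 for the transformed copy (distances are preserved) and near 0
# for the unrelated space: the statistic sees geometry, not coordinates.
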