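"""Score items against a text-style query direction with no model fitting.

In a joint vision-language space a rating question is itself a vector; the
cosine between that query and each item predicts the rating zero-shot.
Here the 'query' is the true population direction of the synthetic world,
standing in for an encoded text prompt.
"""

import traitspace as ts

cfg = ts.SyntheticConfig(n_items=400, n_subjects=40, dims=32, n_categories=8,
                         noise_sd=0.3, seed=3)
E, _ = ts.generate_embedding_space(cfg)
truth = ts.generate_subjects(cfg)
R = ts.generate_ratings(E, truth, cfg)

query = ts.QueryVector("This is a healthy food", truth.healthy_direction)
scores = ts.zero_shot_scores(query, E)

item_ids, mean_ratings = R.mean_ratings("healthy")
aligned = scores[[E.row_index[i] for i in item_ids]]
r = ts.evaluate_zero_shot(aligned, mean_ratings)

print(f"query: {query.label!r}")
print(f"zero-shot correlation with observed mean ratings: r = {r:.3f}")

# r measures how much of the population's mean 'healthy' judgment is
# captured by pure cosine similarity to the query direction, with no
# training data at all.
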