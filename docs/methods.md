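# Methods

## The model

Every analysis in the package rests on one assumption: a subject's rating
of an item is an approximately linear function of the item's embedding
vector.  For item embeddings `X` (items × dims) and a rating vector `y`,
the model is ridge regression

    min_β ‖y − Xβ‖² + λ‖β‖²

with the penalty exactly `λ‖β‖²` — no rescaling of λ by the number of
items, so λ values are comparable across datasets of different size only
with that caveat in mind.  An unpenalized intercept is fitted by centering
columns and targets (rating scales are not zero-centered); it can be
switched off to recover the bare form `ŷ = Xβ`.

Applied to per-item mean ratings this gives the population model; applied
to one subject's ratings it gives that subject's **trait vector** `β_i`,
the direction in embedding space that best explains what they value.  Two
statistics accompany each trait vector:

- `precision_r` (r_i): Pearson correlation between the full-data fit's
  predictions and the observed ratings.  The full-data fit is used
  deliberately — the goal is the most stable direction estimate, not an
  unbiased accuracy estimate — so r_i is optimistic by construction.
- held-out CV r: 5-fold cross-validation accuracy, the honest number for
  "how well can this subject's unseen ratings be predicted".

The tests assert the ordering (full-data precision ≥ held-out CV r in the
median) rather than pretending the two are interchangeable.

**Cosine reading.** When embedding rows have unit norm and the intercept is
zero, `Xβ = ‖β‖ · cos(β, x_j)` row-wise, exactly (asserted to 1e-10 in the
tests).  Fitting a trait vector and scoring items against a query direction
are therefore two routes to the same geometry, and on ratings generated
noiselessly from a query direction the fitted trait recovers that direction
(cosine ≥ 0.99 at n_items ≫ dims).  One caveat found while testing: coarse
8-level Likert quantization is itself a noise source and alone caps the
recovered cosine at ≈0.98 under those settings, so the consistency checks
generate their "noiseless" ratings on a fine integer scale (1000 levels),
and a separate test pins the Likert-8 case at its honestly weaker level
(≥ 0.95).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| λ (`RidgeConfig.lam`) | 1.0 | ridge penalty; conservative on purpose — trait directions should be stable even at a small cost in held-out accuracy. `lambda_sweep_one_se` implements the one-standard-error rule for data-driven selection. |
| `n_folds` | 5 | CV folds; items partitioned uniformly at random (seeded), fold sizes differ by ≤ 1. |
| `rating_rescale` | `unit_interval` | maps Likert 1..L onto [0, 1] before fitting. All reported MSEs are on the fitted scale. Pearson metrics are scale-invariant. Set `none` for raw-scale fits. |
| `feature_normalize` | `none` | optional row L2-normalization; useful when providers emit unnormalized vectors and the cosine reading matters. |

The solver is the SVD of the centered design — stable in the dims ≈ items
regime this package targets (a few hundred rated items against an embedding
of comparable dimensionality).  At λ = 0 the minimum-norm least-squares
solution is returned (singular directions get zero coefficients, relative
threshold `max(n,d)·eps·σ_max`).

## Statistical tests

**Mann–Whitney U.**  U counts pairs `a_i > b_j` plus ½ per tie (computed
via midranks).  For combined n ≤ 12 the p-value is exact, by full
enumeration of all `C(n, n_a)` group assignments of the pooled sample —
this handles ties exactly, which off-the-shelf exact implementations
typically do not.  Above that, a normal approximation with tie-corrected
variance and continuity correction is used; the two agree within 0.02
already at 6+6 in the tests.

**Direction-bias permutation test.**  Each subject's trait is reduced to
its cosine with a reference direction (default: the population healthy
model's β); the statistic is mean(low) − mean(high).  Group labels are
permuted (seeded, vectorized) and the p-value uses add-one smoothing
`(b+1)/(m+1)`, so it is never exactly 0 and is uniform under the null
(checked by KS over 100 seeded runs).  Two-sided by default, matching the
package's general reporting convention; one-sided alternatives are
available.

**Group splits.**  Subjects strictly above the empirical quantile
(`numpy.quantile`, default median) of a questionnaire score go to "high",
ties go to "low".  The cut is an analysis choice, not a clinical threshold;
it is configurable and recorded in outputs.

## The synthetic world

The generator emulates the statistical structure the analysis assumes, at
study-design sizes (896 items, 199 subjects, 8-point Likert scale by
default):

- **Items**: unit-sphere vectors clustered around `n_categories = 16`
  uniformly drawn centroids, isotropic perturbation scaled by
  `1/cluster_concentration = 1/4`, re-normalized.  Unit norm makes the
  cosine/linear equivalence exact and mirrors normalized vision-language
  embeddings; clustering mirrors the category structure real food-image
  embeddings show.
- **Subjects**: per dimension, trait = normalize(`w`·population + (1−w)·
  individual), `w = 0.5`; the three dimensions' individual components share
  a common part (correlation 0.5).  The healthy population direction *is*
  the healthy reference; like/tasty population directions are drawn at
  cosine 0.6 to it — average preference correlates positively with
  perceived healthiness, which gives the picky effect room to move traits
  *away* from the healthy axis.
- **Ratings**: `latent = 0.5·(item·trait) + 0.5 + N(0, noise_sd)` on the
  unit interval (`noise_sd = 0.3` default), mapped affinely onto 1..8,
  rounded half-up, clipped.  Rounding half-up is simple and makes the
  noiseless case an exact monotone transform of the dot product.
- **Group effects**: a picky subgroup (15%) has its like/tasty traits
  rotated within the (trait, healthy) plane so their angle from the healthy
  axis grows by `picky_rotation_deg = 45°`, capped at orthogonality — the
  planted effect models indifference toward the healthy axis rather than
  active avoidance, and the cap makes a 90° rotation land exactly at zero
  alignment.  If a trait is parallel to the reference the rotation plane is
  degenerate and a random orthogonal complement is used.  A high-DSM
  subgroup (15%) keeps unbiased traits but rates with `noise_sd × 2` —
  inconsistency, not directional bias.  Questionnaire scores are synthetic
  stand-ins drawn around group-dependent means (30/55 picky, 15/40 DSM,
  sd 5) so a median split recovers the planted groups.

Effect sizes (rotation angle, noise multiplier, fractions) are calibration
choices — no quantitative values exist for them — fixed once and not tuned.

**What the generator does not emulate:** real embedding geometry beyond
clustered unit-sphere structure (no manifold curvature, no category
hierarchy), item familiarity effects, response styles (extreme/central
tendency), missing ratings, and any nonlinearity in valuation.  Passing
recovery and power tests therefore shows the estimators are correct and
adequately powered *under the linear-valuation model*, not that real rating
data satisfy that model.

## Pre-registered recovery calibration

The trait-recovery check runs the generator at dims = 32, 400 items,
unit-interval noise sd 0.5, 50 control subjects, and asks whether the
median cosine between fitted (λ = 1.0) and true traits falls in a band
fixed in advance.  The band was calibrated with an independent
least-squares oracle (numpy `lstsq` on centered data, λ→0) over five fixed
seeds, giving median cosines 0.444–0.490; the frozen band is
**[0.36, 0.65]** (oracle minimum minus a 0.08 margin, with an upper
plausibility cap).  Ridge at λ = 1.0 tracked the oracle closely
(0.451–0.501) in the calibration runs.

## Problem sizes and numerical choices

- Power simulations use 200 replicates of compact worlds (80 items, 12
  dims; 40+40 subjects for the noise effect, 30+30 for the 45° rotation;
  300 permutations per direction test) — sizes chosen so the whole suite
  runs comfortably on one CPU while keeping Monte-Carlo error on a power
  estimate near 0.8 below ~3 percentage points.
- All randomness flows from one top-level seed through SHA-256-derived
  per-stage `SeedSequence` spawns (`traitspace._rng`), so partial re-runs
  see the same streams; every generator and test is bit-reproducible under
  a fixed seed.
- Ties and degenerate inputs are surfaced, not silently absorbed:
  constant ratings flag undefined correlation (NaN, listed per fold),
  zero-norm rows raise an error naming the item, subjects excluded from a
  group test are listed in the result.
- Distance matrices are symmetrized (`(D+Dᵀ)/2`) and clipped at 0 to absorb
  floating-point asymmetry from the pairwise kernels; distance-triangle
  variance below `1e-12·max` counts as degenerate for correlation.
- Density-weighted stimulus selection weights items by the distance to
  their k-th nearest neighbor (default k = 10) and samples without
  replacement via Efraimidis–Spirakis exponential keys — exactly the
  sequential weighted sampling distribution, which makes inclusion
  probabilities analytically checkable.  This k-NN weight is a simple
  inverse-density proxy chosen for transparency, not a canonical formula.

## Known limitations

- The linear-valuation assumption is shared by model and generator; the
  package cannot detect its own misspecification on real data.
- `precision_r` conflates model fit and rating consistency; a subject with
  perfectly consistent but nonlinear preferences gets a low r_i.
- The pixel baseline flattens resized intensities (bilinear, deterministic);
  it is a distance baseline, not a perceptual model.
- Vision-language providers are deliberately out of the core: the package
  consumes any `EmbeddingMatrix` and never downloads weights or calls
  network services.
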