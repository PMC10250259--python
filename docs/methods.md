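# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data model behind the tests, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## RDMs and 2-D embedding

Dissimilarities are stored condensed (strict upper triangle, 0-based,
lexicographic pair order — the `pdist` convention), with item identifiers
carried alongside. Entries must be finite and non-negative; averaging
requires identical item sets and order.

2-D visualization uses SMACOF multidimensional scaling. The default is
non-metric with Kruskal stress-1 (monotone disparities via isotonic
regression); a metric variant is available through `variant="metric"`
because the two criteria are often conflated in applied reports and we
did not want to guess which one a given study used. The solver runs one
classical-scaling-initialized pass plus `restarts` random restarts
(default 8) and returns the lowest-stress configuration; exactly
embeddable inputs are recovered at stress ~0 by the classical
initialization, which random restarts alone do not reliably achieve.
Stress is re-evaluated from the returned coordinates, so it is invariant
under rigid transforms by construction. Determinism is guaranteed given
the mandatory seed.

## Multi-arrangement estimator

Each trial contributes Euclidean screen distances over the co-presented
item pairs, on an arbitrary per-trial scale. The estimator:

- aligns the trial to the running estimate with the least-squares scalar
  over pairs that already carry evidence (the first trial is normalized
  to unit RMS);
- increments each observed pair's evidence by the squared aligned
  distance (exponent configurable, default 2): pairs placed far apart
  within a trial are better resolved, which is the rationale of the
  inverse-MDS multi-arrangement method;
- updates the estimate as the evidence-weighted mean of aligned
  observations.

Subset selection for the next trial takes the k items with least total
pairwise evidence (ties by item order); the default schedule sets k to
the number of items below the evidence median (floor 3). Sessions stop
when all pairwise evidence reaches a threshold (default 0.5 on the
unit-RMS scale) or a trial budget (default 24) is spent; the original
acquisition software's exact rules are not public, so these are explicit,
configurable stand-ins chosen to emulate a thorough (~2 h) session.

Limitation: every trial is a 2-D projection, so the aggregate cannot
fully recover an RDM whose intrinsic dimensionality exceeds two. On the
default synthetic action space the noiseless single-participant
reconstruction plateaus near τ_A ≈ 0.88 regardless of session length;
the tests freeze ≥ 0.85 as the regression level, and the exactly-2-D
case is verified separately at τ_A ≥ 0.99. Group averages over
participants with independent noise sit in the same range.

## Category discovery

Linkage selection maximizes the cophenetic correlation (Pearson, between
condensed input distances and tree merge heights) over a configurable
method set (default: single, complete, average, weighted); ties keep the
earlier method in the list. The tree itself is always UPGMA, matching the
analysis this package reimplements. The silhouette scan cuts the tree at
k = 3…50 (configurable), computes s(i) = (b−a)/max(a,b) with singleton
clusters scored 0 (Rousseeuw's convention), and picks the k with the
highest mean, smallest k on ties (parsimony). Clusters below `min_size`
(default 2) are dropped and their items reported, mirroring the
singleton-cluster filter used in practice.

## Feature pipeline

Recoding: Yes → 1, No → 0, x ∈ {1…7} → (x−1)/6. Aggregation is the mean
across raters per (action, feature) cell; empty cells are a hard error
rather than imputed, because the emulated design guarantees 7–11 ratings
per action. Redundancy pruning iterates: while any retained pair has
|Pearson r| ≥ threshold (default 0.9) across actions, locate the
worst pair and drop the member with the larger mean absolute correlation
to everything else (ties: later schema order); constant columns are
flagged and excluded from correlation. The procedure logs every removal
and asserts post-hoc that no retained pair crosses the threshold.

The packaged 59-feature / 19-theme schema is a synthetic reconstruction:
the theme names, binary/continuous split (13/6 themes), and
multi/single-feature theme counts (9/10) follow the emulated study
design; individual feature names are plausible completions and should
not be treated as the original rating instrument.

## Category profiles and contrasts

Profiles are per-feature means across a category's actions with 95%
t-intervals (t₀.₉₇₅,ₙ₋₁ · sd/√n). Contrasts standardize the
category-minus-rest mean difference by the Welch combined standard error
across actions; positive z means higher ratings for the category.

p-values default to a label-permutation reference for the Welch z (2000
permutations, vectorized, seeded). This choice is deliberate: mean
ratings of near-binary features are bounded and strongly bimodal
(platykurtic), and at category sizes around 9 actions a normal reference
inflates the per-category family-wise error several-fold, with even the
Welch-t reference measurably anticonservative; the permutation reference
is exact at the test level by construction. Parametric references remain
available (`p_method="t"` or `"normal"`). BH-FDR is applied across the
features within each category (matching per-panel correction); adjusted
q-values use the standard step-up rule.

## RSA with cross-validated reweighting

Model RDMs: single features use the 1-D Euclidean (absolute-difference)
RDM; themes and the unweighted multi-feature model use the joint
Euclidean RDM over their feature columns; the weighted model is the
non-negative linear combination Σ w_f d_f of single-feature RDMs with
weights fit by NNLS — the combination rule of the cross-validated
reweighting literature. Because the unweighted model is a joint Euclidean
RDM rather than an equal-weight linear combination, the weighted model's
in-sample advantage is a statistical expectation, not a per-fold
identity; it is verified statistically on replicate synthetic studies.

Cross-validation: per fold, 10 test actions and 5 test participants are
drawn without replacement (independently per fold); weights are fit to
the training-participant mean RDM restricted to training-action pairs,
and every model's Kendall τ_A is evaluated against the test-participant
mean RDM restricted to test-action pairs. τ_A = (C−D)/(m(m−1)/2) with
ties counting toward neither term; the implementation rescales the exact
tie-counted τ_b statistic and is oracle-tested against pairwise
enumeration. Noise ceilings are computed per fold on the test
participants: upper bound from each participant vs the including-mean,
lower bound vs the leave-one-out mean. Taus, weights and bounds are
averaged over folds; degenerate folds (constant test vector) are skipped
and logged.

Stimulus bootstrap: items are redrawn with replacement; pairs formed by
two copies of the same item (structurally zero distances) are excluded
from all condensed vectors; the full cross-validation is rerun per
sample. Per-model p-values are two-sided tail probabilities of τ ≤ 0,
pairwise model differences are tested on the paired bootstrap
distributions, both families BH-FDR corrected, and p-values are floored
at 1/(n_boot+1). All randomness flows from one seed.

## Synthetic ground truth

The generator defines the study conditions the tests run under: 100
actions in 11 categories (sizes Dirichlet-multinomial, minimum 3), 59
features, 7–11 raters per action, 20 arranging participants.

Feature loadings arise from a 4-dimensional latent space: category
centers are placed by a greedy farthest-point draw (scale 1.0) so that
categories are mutually distinguishable, actions scatter around their
center (sd 0.2), and each feature projects the latents through a random
direction plus feature-unique noise (sd 0.4) and a logistic link (slope
4 for binary features, giving saturated, near-0/1 loadings; 1.2 for
continuous ones). This makes features strongly inter-correlated yet
individually informative, and the true RDM approximately low-rank — the
properties real rating data exhibit (redundant features that need
pruning; group RDMs that embed tolerably in 2-D). Fifteen planted
near-duplicate features (jitter sd 0.02, 30% sign-flipped) emulate the
redundancy the pruning stage removes, reproducing a 59 → ~44 reduction.

The true RDM is the Euclidean distance between loading rows scaled
columnwise by √w*, plus an additive cross-category offset δ = 0.8
(category cohesion beyond what features explain — the reason feature
models need not reach the ceiling). True weights w* are sparse gamma
draws (half zero) with one dominant feature. Raters flip binary answers
with probability 0.05 and jitter continuous ones (sd 0.1 before the 1–7
grid); participants distort the true RDM multiplicatively with lognormal
noise (σ 0.15), keeping distances non-negative, and place items with
arena jitter (sd 0.02, renormalized onto the unit disk).

Weight recovery is assessed against *effective* true weights: a pruned
feature's weight is reassigned to the retained feature it correlates
most with, since near-collinear predictors are identifiable only up to
aliasing.

What the generator does not emulate: response times and fatigue,
rater-specific biases or scale use, semantically structured (non-random)
feature-theme relationships, and any visual properties of stimuli.
Passing tests therefore demonstrate correctness and calibration of the
procedures under a realistic statistical structure, not behavioral
validity on human data.

## Problem sizes and tolerances

Oracle-equivalence tests run on instances with ≤ 15 items / ≤ 3 features
where exhaustive enumeration is exact. The recovery suite runs at the
default study scale (100 actions, 20 participants, 50 folds; 20
replicate studies for the model comparison). Null calibration uses 1000
no-effect studies in the test suite and 300 in the acceptance script,
with 2000 permutations per contrast. Regression thresholds (category ARI
≥ 0.9 at zero participant noise, weight recovery r ≥ 0.8, weighted >
unweighted in ≥ 80% of replicates, |lower ceiling| < 0.05 for
independent participants, null rejection rate ≤ 0.08) are measured
properties of the default conditions, frozen as constants. Numeric
guards: symmetry tolerance 1e−8 on RDM input; MDS convergence eps 1e−11
(tighter in exact-recovery tests); NNLS and BH match their oracles to
1e−9 or better.
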