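# Methods

This note documents the models, procedures and design choices behind
`mirsel`, in the order data flows through the pipeline.

## Synthetic feature tables

Real pre-miRNA benchmarks describe hairpin candidates by >1,000 numeric
sequence/structure features, with a few hundred positives per species and a
shared pool of 980 pseudo-hairpin negatives. The generator
(`mirsel.datagen`) emulates the *statistical* structure of such tables, not
the features themselves. Each column is assigned one role, deterministically
from the seed:

| role        | construction | default share (p = 1000) |
|-------------|--------------|--------------------------|
| informative | N(0,1), positive-class mean shifted by δ_strong = 1.5 SD | 30 |
| weak        | same with δ_weak = 0.3 | 60 |
| redundant   | 20 blocks of 5: `sqrt(r)·z_block + sqrt(1-r)·ε`, pairwise Pearson r = 0.9 | 100 |
| sparse      | `|N(1,1)| + 0.1` with exact 0.0 entries at probability 0.3 per cell | 100 |
| noise       | N(0,1) | remainder |

Every column finally receives a per-column affine map (scale in [0.5, 3],
shift in [−2, 5]; sparse columns are only scaled so their zeros stay exact),
making raw ranges heterogeneous — normalizing them away is the classifiers'
job. Effect sizes are standardized (Cohen's d), so the affine map does not
alter them. Zero inflation is controlled by two separate
parameters: `zero_inflation` (fraction of columns that are sparse, default
0.10) and `zero_prob` (per-cell zero probability, default 0.3), because a
single number cannot control both.

A **study** (`generate_study`) is seven positive tables (sample sizes drawn
once, seeded, from [200, 600] — species sizes are not fixed by any external
source, so the range was chosen to resemble medium-sized miRBase species
collections) plus one shared 980-row negative table, all over the same
feature space and planted roles. Every table and manifest is a pure function
of the configuration; the same seed reproduces bytes.

What the generator does *not* emulate: heavy-tailed and discrete feature
distributions, correlations between informative features and negatives
drawn from a different generating process than positives. Passing tests on
these tables therefore demonstrate correctness and the qualitative
selection/classifier interactions, not performance on real hairpin data.

## Information gain and the selection strategies

IG is computed in bits after equal-width discretization into 10 bins per
feature over its observed range (last bin closed; constant columns collapse
to one bin). Equal-width/10 is the conventional default where the binning
protocol is otherwise unspecified; it is configurable (`n_bins`). All ties
anywhere in the package are broken by ascending feature name, which makes
every selector deterministic given its inputs and seed.

Feature clustering (behind RFC, SFC and HIC) embeds each feature as the
vector of its z-scored per-sample values and runs k-means (k = 100 by
default, seeded, 10 restarts, lowest within-cluster sum of squares kept).
Z-scoring prevents large-scale features from dominating distances. Empty
clusters are retained with size 0.

Selector details that required a decision:

* **SFC** orders clusters by size (descending, ties by the lexicographically
  smallest member) and takes each cluster's *centroid-closest* member; if
  the clusters are exhausted before `m` features are collected, further
  passes take each cluster's next-closest member. Which member to take per
  cluster was genuinely open; the centroid-closest member is the most
  representative single feature of its cluster.
* **RFC** draws one uniform member per non-empty cluster, then a uniform
  `m`-subset of those representatives (all seeded).
* **ZNF** works on raw, un-normalized values of the positive class only:
  any exact 0.0 among positives disqualifies a feature, the rest are ranked
  by their positive-class sum. The generator plants exact zeros so this
  test is meaningful under floating point.
* **PCF** scores each feature by its mean absolute Pearson correlation to
  all other features (pairs involving a constant feature contribute 0) and
  keeps the lowest-scoring `m`. This is the minimal faithful reading of a
  correlation-redundancy filter; fancier correlation clustering would add
  parameters without changing what the benchmark measures.
* **COMBINED** pools per-dataset top-100 lists, ranks features by how many
  lists contain them (ties by mean rank, then name) and keeps the top 50.
  It accepts any list of rankings; the shipped study combines the seven
  per-dataset lists. No consensus is formed for ZNF and PCF.

## One-class classifier

Training uses positive examples only. Features are min-max scaled to [0, 1]
(train-set bounds, test values clipped, constant features mapped to 0);
k-means (default k = 5, seeded, 10 restarts) summarizes the target class;
a sample is accepted as `target` iff its distance to the nearest centroid is
at most a radius τ, otherwise it is `unknown`.

τ is calibrated at a configured quantile q (default 0.95) as the larger of
two candidate radii:

1. the in-sample q-quantile ("higher" interpolation) of all training rows'
   nearest-centroid distances — guaranteeing at least ⌈q·n⌉ training rows
   fall inside τ;
2. a split-conformal quantile: 20% of the training rows are held out of the
   centroid fit, and τ is the ⌈q·(n_cal+1)⌉-th smallest of their distances.
   By the standard conformal coverage argument this makes a *new*
   target-class sample fall inside τ with probability at least q.

The second radius exists because an in-sample quantile alone systematically
under-covers unseen data (the empirical q-quantile bounds new-sample
acceptance by roughly q·n/(n+1) minus the centroid-overfitting gap; measured
0.90–0.95 at q = 0.95), which would make the learner's nominal acceptance
rate unattainable in deployment. With fewer than ⌈q/(1−q)⌉ calibration rows
the conformal rank exceeds the sample and the radius degrades to the
maximum calibration distance. k = 5 and q = 0.95 are defaults, not facts
about any external dataset; both are configurable and recorded in all
outputs.

## Two-class classifier

A soft-margin SVM with RBF kernel `exp(−γ‖u−v‖²)`, γ = 0.7 and C = 4.0, on
min-max-normalized features of both classes (scikit-learn's SVC provides
the optimizer; the kernel, hyperparameters and normalization are fixed by
the benchmark protocol, the optimizer is not). Trained models store support
vectors, dual coefficients and the intercept explicitly, and predictions are
evaluated from those arrays, so a serialized (JSON) and reloaded model
predicts identically.

## Cross-validation and metrics

* OCC: 100 Monte-Carlo repetitions by default. Each fold samples 90% of the
  positives for training; the test set is the held-out 10% plus *all*
  negatives, injected as the unknown class (they never enter training).
* TCC: 10 repetitions, 90/10 splits drawn per class (stratified — plain
  random splits can produce single-class training sets at small n).
* Fold seeds derive from (seed, fold index), so any fold reruns in
  isolation.

Per fold a confusion matrix is kept (positives = target class); folds
aggregate to means and sample standard deviations (n−1) of SE, SP, pooled
accuracy and balanced accuracy. Because the OCC protocol pits ~10% of a few
hundred positives against 980 negatives, pooled accuracy is dominated by
the negative class; balanced accuracy (SE+SP)/2 is therefore the headline
"ACC" throughout, with pooled accuracy reported alongside. The comparison
table is `TCC_ACC − OCC_ACC` per (dataset, method) with an Average row,
method columns sorted by increasing average difference.

## Problem sizes

The shipped study defaults are 7 datasets × 1,000 features with 980 shared
negatives. The test suite and `scripts/acceptance.py` run the full study at
20 OCC / 5 TCC folds — enough repetitions for stable means (fold-to-fold
standard deviations are reported, and the end-to-end run stays below a few
minutes on a single CPU); individual analyses use the 100/10 defaults.

## Known limitations

* Gaussian single-feature signal means selection methods that exploit
  distributional quirks of real features (ZNF in particular) are exercised
  structurally but not challenged realistically; on these tables ZNF's
  candidate set is essentially "the non-sparse columns".
* Negative-control selections (LIG, and PCF on these tables) pick columns
  with literally zero class signal, so both learners fall to chance there —
  sharper than on real data, where even poorly chosen features retain some
  signal. The *direction* of the OCC/TCC contrast is the reproducible
  finding, not its magnitude.
* The one-class learner assumes the target class is representable by a
  small number of spherical clusters in normalized space; strongly
  manifold-shaped positive classes would need a larger k or a different
  one-class model.
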