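# Methods

This note records the model, the numerical choices, and the open design
decisions behind `evicomb`, in the order the pipeline runs.

## Belief-function algebra (`ds_core`)

Subsets of the frame are bitmasks over the frame's fixed class order,
giving exact set identity and O(1) intersection.  All BBAs are *normal*
(no mass on the empty set); the pignistic transformation therefore omits
the 1/(1 − m(∅)) normalization that an open-world model would need —
every BBA this package produces is a softmax over nonempty classes, so
the factor is always 1.

Numerical choices:

- `make_bba` renormalizes mass sums that deviate from 1 by at most 1e-6
  (accumulated floating-point error) and rejects anything larger as a
  user error.
- Combination treats conflict K ≥ 1 − 1e-12 as non-combinable: the paper
  condition is existential (some pair of focal elements must intersect),
  but near-total conflict makes 1/(1 − K) catastrophically cancelled, so
  it is rejected with the measured K in the error.
- Masses below 1e-15 after a combination are dropped and the BBA
  renormalized, bounding focal-set growth in long fusion chains.
- `combine_all` folds pairwise; associativity of the orthogonal sum
  makes this exact, and memory stays bounded by the focal count.

## Expert networks (`experts`)

Experts are one-hidden-layer networks with logistic hidden and output
units, trained by plain gradient descent on a sum-of-squares loss
against 0/1 targets.  The gradient is accumulated over the epoch and
applied once (classic batch backpropagation); at the same learning rate
this takes steps comparable to the per-sample rule, and it is fully
vectorized and deterministic.  Weights initialize uniformly in
[−0.5, 0.5] scaled by 1/√fan-in from a seeded generator; two runs with
the same seed produce bit-identical weights.

Early stopping watches the validation set each epoch, restores the best
weights, and stops after `patience` (default 30) checks without
improvement beyond `tol` (default 1e-4).  The monitored quantity is
configurable and this matters:

- `monitor="loss"` (default) watches validation mean squared error.
  The confidence-relabeling template needs *calibrated* output
  confidences, and accuracy saturates long before the outputs sharpen —
  on well-separated data a network can be 100% accurate at epoch 30
  with outputs still near 0.5, which would poison the template.
- `monitor="accuracy"` watches decision accuracy (projected onto the
  original classes through a pignistic-style spread when soft output
  nodes exist) and is used for the decision experts of every combiner,
  evidential and fixed-rule alike, so the comparison is symmetric.

When a crisp class was entirely relabeled away, validation samples of
that class have no output node; they are excluded from the loss monitor
and scored through the spread projection in the accuracy monitor.

Eq-9-style BBA extraction applies the softmax to the raw output
activations by default (`on="raw"`); applying it to the logistic
outputs instead (`on="logistic"`) is one keyword away.  The raw basis
preserves the network's full discrimination; the logistic basis bounds
any single view's mass ratio by e and is the more literal reading of
"softmax of the outputs".  Both are exposed because the source
presentation does not settle the question; the default was chosen for
its sharper per-view evidence.

## Confidence relabeling (`relabeling`)

The published form of the confidence function is not legible in the
source material; the implementation uses

    v_i = (d_min + ε) / (D_i + ε),   ε = 0.01,

which satisfies every stated property: v = 1 at the smallest gap,
strictly positive at D_i = 0 (the ε prevents 0/0), and strictly
decreasing in the gap.  `RelabelConfig.confidence_fn` accepts any
replacement with the same signature.

The clamp "a class the network exceeds its template on is confident" is
applied elementwise: if two classes both exceed their template values,
both get v = 1 and jointly form a soft label.  The narration describes
a single confident class; the uniform rule coincides with it whenever
only one class qualifies.  Crisp assignments take the argmin-gap class
(ties to the lowest index), which follows the relabeling network's
decision rather than the original label — on separable data the two
coincide (the package asserts ≥ 99% agreement at side 10), on
overlapped data the relabeling is precisely the point.

The KNN-relabeling baseline needs a similarity between a sample and a
local class prototype; the source leaves it unspecified, so
1/(1 + Euclidean distance) is used and documented as configurable.
Soft classes are ordered canonically — crisp singletons first, then
soft labels by member tuple — so expert output-node semantics are
reproducible.

## Ensemble and baselines (`ensemble`)

At prediction time the per-view BBAs are folded left to right; a BBA
whose inclusion would make the running conflict total is skipped with a
warning instead of failing the prediction (the source never addresses
K = 1 at test time, and dropping one view's evidence is the least
destructive recovery).  Ties in the pignistic argmax go to the lowest
class index.

Fixed-rule experts are trained on the original labels with the same
architecture, training rule and early-stopping monitor as the
evidential decision experts, mirroring the comparison protocol.
Decision templates are class-mean decision profiles matched by squared
Euclidean distance.

## Feature-subspace selection (`feature_selection`)

The printed form of the diversity measure is unreadable in the source;
Kuncheva's non-pairwise inter-rater agreement

    κ = 1 − Σ_j l_j (L − l_j) / (N L (L−1) p̄ (1 − p̄))

is implemented (the measure the source cites), with κ defined as 1 when
p̄ ∈ {0, 1} — a pool that is always right or always wrong carries no
diversity information.  Forward search seeds with the most accurate
classifier and greedily adds the candidate minimizing the committee's
κ; ties break by higher accuracy, then lower index.  Greedy stepwise
selection is not globally optimal, so on rare pools the selected
committee's κ can exceed the naive top-accuracy committee's; the tests
assert dominance on ≥ 90% of random pools and on average rather than
universally.  Directed random subsets sample k indices per channel
block; a one-block layout reduces to a plain random subset.

## EEG stages (`eeg_features`)

- Surface Laplacian: channel minus the mean of its four mapped
  neighbours; unmapped channels pass through with a warning.
- Band-pass: 6th-order Butterworth applied forward-backward
  (zero-phase) — classification here is offline, so the doubled
  attenuation and zero lag are preferable to causal filtering.
- Epochs are half-open sample windows `[round(t0·fs), round(t1·fs))`,
  0-based, measured from stimulus onset.
- CSP: per-trial spatial covariances are trace-normalized before
  class-averaging (amplitude invariance across trials); the one-vs-rest
  generalized eigenproblem is solved per class with a trace-scaled
  ridge (default 1e-8) on the composite matrix, keeping the first and
  last m eigenvectors.  m defaults to 3, the value forced by the
  standard 4-class recipe's 24 features (C·2m = 24); it is a plain
  parameter.  Features are log(var_j / Σ var) along each filter, with a
  plain elementwise log variant available.
- PSD: Welch/periodogram over the trailing window (default 1 s), bins
  sampled at multiples of the resolution (default 2 Hz) across the band
  (default 8–30 Hz), channels concatenated — 12 bins × 8 channels = 96
  dimensions in the reference recipe.  Unit-length normalization and
  first-of-k downsampling complete the precomputed-feature path.

## Synthetic data (`synthetic_data`)

The triangle benchmark places class means on an equilateral triangle
(centroid at the origin, vertex 1 on the positive y-axis, numbered
clockwise) with identity covariance; views 2 and 3 advance every class
mean one vertex clockwise.  Labels are shared across views while the
coordinates are drawn independently per view: the benchmark's premise
is that a sample overlapped in one space can be cleanly placed in
another, which independent draws maximize.  Default totals are
150/300/500 for train/validation/test, split as evenly as possible
among the three classes with the remainder going to the lowest class
indices.  Side lengths 1/2/3 operationalize high/medium/low
uncertainty; the tests anchor these by nearest-mean accuracy (< 0.75 at
side 1, > 0.99 at side 10).

The trial generator drives band-limited Gaussian sources (default
8–13 Hz, the mu band) along per-class spatial patterns with
class-specific powers, over white sensor noise.  It emulates the
spatial-variance structure CSP exploits and nothing else: no artifacts,
no non-stationarity, no volume-conduction geometry.  Tests passing on
it show the feature stages recover planted structure, not that they
would rank methods identically on recorded EEG.

## Benchmark protocol (`pipeline`)

`run_artificial_experiment` generates the views per condition and seed,
fits every requested method, and scores the held-out test set.  The
evidential methods tune θ per run by validation accuracy over a coarse
grid — every 0.1 across the printed 0.05–0.95 range; the full
0.005-step grid can be passed explicitly.  All methods share one
network configuration per run: 15 hidden units (mid-range of the 2–20
tuning band), learning rate 0.1, up to 1000 epochs with patience 60 —
desk-scale defaults chosen so a full 3-condition × 10-seed run with all
methods completes in a few minutes on one CPU; the report is
bit-reproducible given the seeds.  Per-run failures are logged and
excluded with a count in the report.

## Known limitations

- The expert is a fixed one-hidden-layer topology with plain gradient
  descent; no momentum or adaptive optimizers, by design.
- Dempster fusion cost grows with the number of focal elements; with
  the ≤ 2^C classes a relabeled view can produce this is negligible for
  the C ≤ 4 problems targeted here, but the package makes no effort to
  scale to large frames.
- The KNN-relabeling baseline is evaluated at a fixed threshold rather
  than a tuned one; it serves as a reference point, not an optimized
  competitor.
- No loaders for BCI-competition native formats; trial sets are
  exchanged as TSV manifests.
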