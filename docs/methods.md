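# Methods

This note documents the models, conventions and design choices behind
`coreselect`, in the spirit of a statistical package's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Given *N* unlabeled items embedded as real vectors, an annotation
budget *M*, and (for some strategies) a prior on the number of classes
*C*, select *M* items whose labels will best support training a
classifier. The working assumption is that a good feature extractor
maps same-class items near each other, so geometric diversity in
embedding space is a usable proxy for semantic coverage. All distances
are Euclidean, and clustering operates on raw (unnormalized) embeddings
by default; `l2_normalize` is available but off, since nothing in the
method requires unit-norm features and normalization changes the
geometry being clustered.

## K-means

`coreselect.cluster` implements Lloyd's algorithm with k-means++
seeding. Parameters and defaults:

- `k` — number of clusters; fixed in advance, as the method requires.
- `n_init = 10` — independent seedings; the best model by inertia is
  kept. Restarts damp the initialization variance that repeated-split
  experiments otherwise average over.
- `max_iter = 300`, `tol = 1e-4` — iteration stops when assignments are
  stationary or the relative inertia improvement falls below `tol`.
  With `tol = 0` the algorithm runs to a true fixed point, at which
  each centroid equals its members' mean (enforced to 1e-9 in tests).
- Ties in the assignment step go to the lowest cluster index; distances
  use the expanded form ‖x‖² − 2x·c + ‖c‖² clipped at zero, which keeps
  exact ties exact on integer-valued fixtures.
- Empty clusters are repaired by relocating the empty centroid onto the
  point currently farthest from its assigned centroid and reassigning;
  bounded passes guarantee termination. Selection requires K non-empty
  clusters, which is why repair is part of the model contract rather
  than best-effort. The single unreparable case — fewer distinct points
  than clusters — is left as-is and documented on the function.

Correctness is checked against an exhaustive-partition oracle (all k^N
labelings, N ≤ 10) rather than against another library: best-of-20
restarts attains the global optimum on ≥ 95 of 100 random instances and
can never beat it; the recorded inertia history is non-increasing.

## Selection strategies

- `K_EQ_IMAGES` (K = M): one uniform draw per cluster. Maximally
  spreads the budget; the reference configuration.
- `K_EQ_CLASSES` / `K_EQ_2CLASSES` (K = C or 2C): per-cluster quotas
  from an even-split rule: base ⌊M/K⌋ everywhere, the M mod K leftover
  one-each to the largest clusters (ties by index), quotas capped at
  cluster size with the deficit redistributed one draw at a time to the
  cluster with most remaining capacity. When all clusters are large
  enough, allocations differ by at most 1.
- `RANDOM`: uniform without replacement; the baseline.

Within-cluster draws are uniform by default; a `nearest` (to-centroid)
mode exists but is non-default, since uniform draws better preserve
within-cluster variability.

The retention-fraction → subset-size conversion exposes both integer
conventions seen in published subset tables: `floor` (default) and
`nearest` (half away from zero). For a 48 875-item pool the floor
convention yields 146 / 2 443 / 14 662 items at 0.3% / 5% / 30%; for a
6 633-item pool at 10% both conventions agree on 663. The two
conventions genuinely disagree on some published rows (e.g. 30% of
6 633 is 1 989 under floor, 1 990 under nearest), which is why the
choice is an explicit argument rather than hidden.

## Seeds

All randomness flows from one integer seed. Stages derive sub-seeds by
hashing a stage tag (BLAKE2b) into an offset modulo 2³¹ − 1, so pipeline
stages are individually reproducible and never share streams. Within
the benchmark, the classifier seed and the train/validation split
depend on (repetition, fraction) but deliberately not on the strategy:
two strategies that select the identical set (e.g. any strategy at
retention 1.0) must produce bit-identical scores. For the same reason
the coreset is put into canonical (sorted-id) order before the
validation split, making the split a function of the selected set
rather than of selection order.

## Synthetic embedding clouds

`generate_blobs` emulates the geometry the method assumes: each class
is an isotropic Gaussian mode (sd `noise_sd`, default 1) around a
centroid on a hypersphere of radius `separation × noise_sd`;
`submodes_per_class > 1` splits a class into several modes offset by
half that radius, mimicking intra-class variability. Per-class counts
are exact by construction; a built-in profile reproduces the 38-class
PlantVillage count distribution (152–5 507 images per class, 37×
imbalance), and the standard study pool in tests and the acceptance
script uses that profile scaled down 10× (5 429 items) with
`separation = 8`, `dim = 32` — desk-scale sizes at which the full
benchmark runs in seconds per seed on one CPU.

Centroid placement is uniform on the hypersphere with a
minimum-spacing rejection step (target spacing equal to the radius,
halved whenever a retry budget is exhausted). Pure uniform placement
can drop two class centroids arbitrarily close together — in 2
dimensions with non-negligible probability — which would make
"separation" misleading as a difficulty knob; the rejection step
restores the intended monotone link between `separation` and
nearest-centroid separability while leaving high-dimensional placement
essentially uniform (random directions there are nearly orthogonal, so
the constraint is almost never active). At `separation ≥ 8` with one
mode per class, a nearest-centroid rule on the true means is ≥ 99%
accurate (checked by simulation).

What the generator does **not** model: background clutter, label noise,
non-Gaussian class shapes, class overlap structure, or any pixel-level
phenomenon. Passing tests on this substrate show that the pipeline
exploits cluster structure correctly when it exists; they do not show
that a particular real extractor produces such structure — that is what
the validity indices are for on real embedding tables.

## Evaluation

- **Macro-F1** is the unweighted mean of per-class F1. A class with
  zero precision and recall scores 0 and is logged. In the benchmark
  the average runs over the classes present in the test ground truth;
  predictions of other classes simply count against the true class.
- **Davies-Bouldin** and **Silhouette** follow their standard
  definitions with Euclidean distance (a singleton's silhouette is 0 by
  convention). Both are validated to 1e-9 against an independent
  reference implementation and against hand-computed fixtures
  (two `{(0,0),(0,1)}`-style pairs 10 apart give exactly 0.1 and
  1 − 2/(10 + √101) ≈ 0.90025).
- **Benchmark**: per repetition, a fresh 10% test split; the remaining
  pool is reduced by each (fraction, strategy); the classifier trains
  on 90% of the coreset with 10% validation; macro-F1 on the test split
  is aggregated as mean ± sample standard deviation (n − 1; reported as
  0 for a single repetition).

The default classifier is a deliberately simple stand-in for image
fine-tuning: multinomial logistic regression trained by full-batch
gradient descent for a fixed 200 epochs at step 0.1, seeded Gaussian
init, keeping the weights with the lowest validation loss. Features are
standardized with training-set statistics inside the classifier — raw
synthetic embeddings have coordinate scale of order `separation`, and
fixed-step gradient descent is only well-behaved on standardized
inputs. The trainer contract (`fit(X, y, X_val, y_val)` / `predict`) is
pluggable so an image-based trainer can be substituted without touching
the benchmark.

Benchmark runs on the study pool use `n_init = 1`, `max_iter = 100` for
the K-means inside selection (K reaches ~1 466 at 30% retention, where
restarts are unnecessary: with that many centroids the seeding variance
is negligible relative to the effect being measured).

## Known limitations

- At budgets below the class count (M < C) every strategy is capped at
  roughly M/C of the achievable macro-F1, so the coreset-vs-random gap
  compresses; the advantage is largest when M is a small multiple of C.
  On the 10×-scaled study pool this regime begins below ~0.7%
  retention.
- K-means with K = M becomes expensive for very large budgets; the
  implementation is plain Lloyd (no mini-batching or triangle-inequality
  pruning).
- The class-based strategies assume the class count is known for an
  unlabeled pool; when the prior is wrong the quotas are still valid,
  but the diversity argument for K = C weakens.
- The embedding file dialect stores full-precision decimal text: exact
  and diff-able, but ~2.5× larger than binary.
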