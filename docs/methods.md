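# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## The prediction problem

Input is a binary bipartite matrix `Y` (n diseases × m microbes) built from
a curated edge list; `y_ij = 1` records a known association. Matrices of
this kind are sparse (HMDAD-scale data is ~4% dense) and one-sided: absence
of a link means *untested*, not *negative*. The pipeline therefore has to
solve two problems at once — extract pair features that carry association
signal, and manufacture a trustworthy negative class for supervised
training.

## Similarity and fusion

The association-profile kernel `G_ij = exp(−θ‖V_i − V_j‖²)` compares binary
profiles (rows of `Y` for diseases, columns for microbes) with bandwidth
`θ = n / Σ_i‖V_i‖²`, i.e. the reciprocal of the mean squared profile norm.
This normalisation makes the kernel scale-free: denser networks get a
narrower kernel. An all-zero `Y` leaves the bandwidth undefined and is
rejected.

Externally computed functional similarity (e.g. genome co-occurrence for
microbes, shared-gene similarity for diseases) can be supplied as a named
square matrix. Fusion averages functional and kernel similarity entrywise
where the functional entry is non-zero and falls back to the kernel
elsewhere. The non-zero test is exact (no tolerance): functional matrices
are sparse, and a structural zero means "no information", not "dissimilar".
The fused diagonal is forced to 1. With no functional input the fusion
equals the kernel exactly, which is the default operating mode.

## Graph attention autoencoder

Each side's fused similarity matrix is sparsified to a k-nearest-neighbor
graph (default k = 10, self-loop always included, ties to the lower index —
a deterministic rule, since the dense similarity matrix itself defines no
neighborhood). Node attributes default to association profiles (`Y` rows /
columns); a `similarity` option uses the fused similarity row instead. The
profile default makes the pair features carry association signal directly
and keeps the decoder's targets binary-like.

One encoder layer maps attributes to 64-dimensional embeddings and one
mirrored decoder layer maps back (depth is configurable; stacking works but
one layer is the default because the added depth buys little on matrices
this size). Attention logits use a sigmoid, transforms use tanh — the
zero-centred transform keeps the embedding inner products in the structure
loss well behaved. The loss is

    L = Σ_i ‖x_i − x̂_i‖² − λ Σ_i Σ_{j∈N_i} log σ(h_iᵀh_j),

with λ = 1 by default. Training is full-batch Adam (lr 0.001, 200 epochs by
default), with hand-derived gradients; the test suite checks them against
central finite differences at 1e-6. Initialisation is seeded Glorot-uniform;
given a seed, training is bit-reproducible. Non-finite losses or activations
raise immediately with the epoch or layer named.

## Reliable negatives by PU learning

Spies are the `⌊t·|P|⌋` positives (at least 1) closest to their own K-means
centroid (default 5 clusters over positives only — only members of `P` are
eligible as spies), with `t = 0.15` by default and `0.20` recommended for
Disbiome-scale data. Central positives are chosen deliberately: a randomly
drawn spy can be an outlier of `P`, and an outlier's score floor says
nothing about where genuine positives live.

The scorer is an XGBoost classifier (100 trees, depth 6, lr 0.1, single
thread, seeded) fit with `P−S` as class 1 and `U+S` as class 0. **Scores
are out-of-fold**: pairs are split into 5 score folds and each fold is
scored by an ensemble fit on the others. Scoring pairs with a model that
saw them in training lets the ensemble memorise the spies' provisional 0
labels — measured on planted ground truth, in-training scoring drives
`A_min` to ~0.003 and sweeps ~90% of `U` below it, which contradicts the
premise that most unknown pairs should remain unknown after selection.
Out-of-fold scores measure what the classifier *believes* about a pair
rather than what it was told, and restore a meaningful threshold.

`A_min` is the minimum spy score; `RN` is every unlabeled pair scoring
strictly below it (ties stay unlabeled). `|RN|` is data-driven and never
forced to match `|P|`.

## Classifier

A feed-forward network with layers 128→100→100→50→1, ReLU hidden units,
dropout 0.2 after each hidden layer, sigmoid output, binary cross-entropy,
mini-batch Adam (lr 0.001, batch 32, 300 epochs by default; larger corpora
benefit from ~1,500). The input width follows the pair-feature width
automatically. Training is seeded and deterministic; inference disables
dropout and returns scores clipped into the open interval (0, 1). Class
imbalance is left as-is by default (`|RN|` is threshold-driven); a balance
option subsamples the majority class.

## Cross-validation and leakage control

Three schemes: held-out pairs (20% of all n·m pairs), held-out diseases,
held-out microbes (cold start). For every fold the held-out associations
are zeroed in the training matrix and *everything* is recomputed from the
masked matrix — kernel similarity, graphs, embeddings, PU selection,
classifier. Two deliberate controls go beyond the obvious masking:

* Kernel similarity is computed per fold from the masked matrix, never once
  from the full matrix, so held-out links cannot shape the features.
* Held-out test pairs are excluded from the classifier's negative training
  pool (both the reliable-negative set and any random-negative baseline).
  Scoring all pairs during PU selection is transductive and harmless, but
  *training* on the very pairs being tested — even with presumed-negative
  labels — lets the network memorise the test set; with ~96% of test pairs
  truly negative that memorisation inflates AUC spuriously.

Test positives are the held-out known links, test negatives all other
held-out pairs. Folds whose test set is single-class (possible for
cold-start schemes on sparse data) are skipped with a warning, not failed.
AUC is the Mann–Whitney probability (ties half), AUPR is average precision;
both delegate to scikit-learn and are checked against an O(n²) enumeration
oracle in the tests.

The PU ablation runs each fold twice — Algorithm-1 negatives vs a uniform
random unlabeled sample of the same size, all else shared — and reports the
paired difference.

## Synthetic data: what it shows and what it cannot

The generator draws nonnegative rank-r factors with dominant-block
structure, forms propensities `P ∝ UVᵀ`, and thresholds at the quantile
matching the target density (defaults: 40 diseases × 120 microbes, rank 4,
density 0.04, no noise — an HMDAD-scale regime). Because every pipeline
stage assumes profile similarity predicts links, this gives a truthful
positive control (pair-scheme CV reaches AUC ≈ 0.93) and a clean negative
control (shuffling the matrix collapses AUC to ≈ 0.5).

Two honest limitations:

* **Cold-start schemes are weak without side information.** A held-out
  disease or microbe has an all-zero profile in training, so its kernel row
  and attributes carry almost nothing; with no functional similarity
  supplied, disease-scheme AUC sits modestly above chance and microbe-scheme
  AUC at chance. Real deployments should supply functional matrices for
  cold-start use.
* **The PU ablation is a statistical tie on closed-world synthetic data.**
  The benefit of reliable-negative selection comes from avoiding hidden
  positives in the unlabeled pool. In a synthetic world the evaluation
  ground truth *is* the generated matrix, so (after the held-out pairs are
  excluded from training) every unlabeled training pair is an
  evaluation-negative; selection can only discard informative hard
  negatives, and the measured paired AUC difference is ~0 (slightly
  negative, within ~0.01–0.04 across fold seeds). A directional advantage
  for PU selection requires incompletely annotated data, which is exactly
  the situation in real association databases and exactly what a
  self-consistent generator cannot express. The recovery benchmarks that
  *can* be posed in a closed world (planted two-Gaussian ground truth:
  reliable-negative precision ≥ 0.99 at 4σ separation, precision ≈
  true-negative prevalence at 0σ) pass.

A second generator plants PU ground truth directly: pair features from two
Gaussians separated along one coordinate by a configurable number of
standard deviations, 40% positives of which half are labeled, the rest
hidden in `U`. It exists to score reliable-negative recovery exactly.

## Problem sizes and runtime

CV-level checks and the acceptance script use a reduced-epoch profile (100
autoencoder epochs, 100 classifier epochs per fold) on the default 40×120
conditions; one five-fold pass takes under a minute on one CPU, and the full
acceptance script about four minutes. Library defaults remain 200/300
epochs. All randomness flows from one master seed fanned out per stage by
name hashing (CRC32, kept below 2³¹), so any stage rerun with the same seed
is bit-identical.

## Known limitations

* No taxonomy or ontology normalisation: names are matched by trimmed,
  case-folded string equality only.
* Functional similarity is consumed, never computed.
* Single-head attention; nodes absent at training time cannot be embedded
  without refitting.
* No hyperparameter search, ensembling, or probability calibration.
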