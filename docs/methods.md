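# Methods

## Architecture

The functional hierarchy is a leveled DAG with gene nodes at level D,
pathways at C, pathway groups at B, top categories at A and one output node
O; edges connect adjacent levels only, and multi-membership (a gene in
several pathways, a pathway in several groups) is allowed and preserved —
the wiring fans out and relevance later sums over the same fan-out. Before
model construction the hierarchy is pruned to the intersection with the
measured genes: unmeasured genes are dropped and any module left childless
is removed, cascading upward (never removing O). No minimum module size is
enforced; a single-gene pathway is a legitimate module.

Each C/B/A/O node is a module: a dense stack with layer widths `[3, 3, 3]`,
tanh on the first two layers and identity on the last, plus a linear
classifier head. The first internal layer maps the concatenated child
outputs to 3 neurons; this block is what the L1 "module-input-layer"
penalty and the bias exclusion refer to. Bias layout: no bias on the first
internal layer and the head; the middle layer keeps a bias; the identity
layer carries none either, mirroring the head so that the linear tail of
each module stays bias-free (this measurably improves the exactness of
relevance conservation, since bias relevance is absorbed rather than
redistributed). Weights are normalized-Xavier initialised,
`U(±sqrt(6/(fan_in+fan_out)))`, biases start at zero, and a fixed seed
makes construction bit-reproducible.

## Training

The objective is the weighted multi-loss: per-module class-weighted
cross-entropy (automatic weights `n/(K·n_c)`; a manual map is accepted),
summed within each level, scaled by the level weights (defaults C 1.3,
B 1.2, A 1.1, O 1.0) and summed over the levels active at the current
epoch (inclusion defaults C:1, B:2, A:4, O:6, 1-indexed). Within-level
aggregation is a sum by default; `layer_reduce: mean` is available for
hierarchies whose level sizes are very unequal, where a mean preserves the
intended 1.3 → 1.0 priority. Inactive levels are fully frozen: their
parameters receive no gradient from any term, including the L1 penalty,
which is what makes the progressive schedule meaningful (verified by a
finite-difference test). Because inactive levels sit strictly above active
ones in the DAG, no gradient path reaches them anyway; the implementation
skips them explicitly and the L1 penalty is likewise restricted to active
modules.

L1 penalties are 0.1 per first-internal-layer weight block and 0.01 on
every other weight (the two multipliers are disjoint — 0.1 is not added on
top of 0.01); biases are exempt. The optimiser is Adam at learning rate
0.01 by default (plain SGD via config); the learning rate is the quantity
with published support, the optimiser choice is exposed rather than
hidden. Batch size defaults to 32 (16 is the natural choice for cohorts of
a few hundred samples), `max_epochs` to 30 with no early stopping.

Gradients are computed by explicit reverse-mode differentiation over the
module DAG in NumPy. The modules are tiny dense stacks, so a hand-written
backward pass is both faster than a framework at this scale and exactly
reproducible single-threaded.

Model selection: after every epoch the validation multi-loss is computed
over *all* module layers, ignoring the inclusion mask, so that values are
comparable across epochs; the checkpoint with the lowest validation loss
wins, ties going to the earliest epoch. Reported predictions always come
from the O head; auxiliary heads only ever contribute loss.

## Cross-validation

Stratified k-fold (default k = 10): within each class, samples are
shuffled by seed and dealt into k chunks of size ⌈n_c/k⌉ or ⌊n_c/k⌋ with
the larger chunks on the lowest-index folds; fold f is the union of chunk
f over classes. For a 434/555 cohort this yields fold sizes
5×98, 1×99, 4×100 with every fold's class ratio within one percentage
point of the cohort's. This deterministic remainder rule is a design
choice; it is incompatible with a literal leave-one-out partition at
k = n under ≥2 classes, which we accept. Per split, two validation folds
are drawn without replacement from the non-test folds using a
split-derived seed (base seed + split index).

Mean-centering of expression rows defaults to training-fold statistics
re-applied to validation/test folds (`center: train_only`); `global`
centers the full matrix once, which is the simpler but leak-prone variant,
and is provided for fidelity with pipelines that center before splitting.
Centering is per-gene; per-sample centering is exposed in the library
(`mean_center(..., axis="sample")`) since either reading of "mean reduced"
is defensible, and per-gene is the one that reduces LRP relevance
absorption.

Metrics (per split and pooled over all test folds): per-class precision
and recall, macro F1, balanced accuracy (mean per-class recall), MCC, and
the confusion matrix; the split summary reports median/mean/std/min/max.
F1 is macro-averaged — symmetric in the classes. Implementation sits on
scikit-learn; tests cross-check against a brute-force confusion-matrix
oracle.

## Relevance and biomarkers

LRP uses the epsilon rule at every linear layer; nonlinearities pass
relevance through unchanged. Defaults: ε = 1e-6 (exposed; ε = 0 gives
exact conservation on bias-free nets, tested to 1e-6 relative over random
networks); relevance is seeded with the raw pre-softmax O-head score of
the start class (softmax-seeded variants were deliberately not added — the
raw score is standard practice); the start class defaults to the model's
prediction for that sample, with per-true-class and fixed-class modes
available. A neuron with an exactly zero pre-activation at ε = 0 passes on
no relevance (guarded division). Auxiliary heads of C/B/A modules never
carry relevance. Module relevance is the sum over the module's last-layer
neurons; per-sample maps are normalised by the absolute sum within each
level — genes included, uniformly with the module levels — so maps are
comparable across the k cross-validation models, then pooled.

Biomarker calling: within each level, the threshold is
τ = mean + sample standard deviation (ddof = 1) of all pooled
(node, prediction) normalised values; a node is flagged when its median
strictly exceeds τ and is positive. The positivity constraint reflects
that positive relevance is what supports the predicted label. A per-node
variant (τ from the node's own values, plus a grand-mean-of-medians gate)
is available as `threshold_mode: per_node` because the threshold scope is
genuinely ambiguous; pooled-per-level is the default as the stricter and
more comparable rule.

## Synthetic data

The generator emulates post-normalisation log-scale expression: background
values i.i.d. `N(0, σ²)` in both classes, a chosen set of planted genes
shifted by `+δσ` in the second class, exact class counts (imbalance
allowed), and a hierarchy built by round-robin assignment with optional
Poisson multi-membership (mean parents per node = `membership_fanout`;
childless parents adopt a child so the hierarchy always validates). An
optional AR(1) correlation within pathways stresses explanation
robustness; off by default. Defaults (200 genes, 20 pathways, 6 groups,
2 categories, 10 planted genes at δ = 3σ, 100 + 100 samples) are the
reference study conditions for the recovery and null experiments. What
passing these tests shows: the pipeline recovers strong planted
mean-shift signal and stays quiet under the null. What they do not show:
robustness to count overdispersion, batch effects, probe-level artefacts
or correlated confounders — real-data properties the generator does not
model.

## Problem sizes and determinism

The test suite runs the full pipeline at the reference conditions (ten
splits, 30 epochs, ~29 modules) in roughly ten seconds per seed on one
CPU; unit tests use 20-gene fixtures. All randomness flows from explicit
seeds through `numpy.random.default_rng`; training, fold assignment and
simulation are bit-reproducible single-threaded, which is the default and
tested mode.

## Known limitations

- Two-level-of-interest explanations only: relevance is seeded at one
  class at a time; contrastive (class-difference) seeding is not
  implemented.
- Only the epsilon LRP rule is provided; αβ/γ/z⁺ rules are out of scope.
- The checkpoint format stores parameters as JSON lists — convenient and
  diff-able for these tiny models, inappropriate for large ones.
- Inputs must be complete; missing values are load errors by design.
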