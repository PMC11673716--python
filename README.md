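# xmodnn

Explainable modular neural networks for biomarker and pathway-relevance
discovery in transcriptomic classification tasks.

## The problem

Transcriptomic cohort studies routinely need to classify samples (disease
state, cell state, clinical parameter) from thousands of gene expression
values measured on a few hundred subjects — and then explain *which* genes
and pathways drove the decision. Fully connected networks overfit badly in
this regime, and post hoc attributions on them are unstable. `xmodnn`
addresses both problems by building the network *out of* a functional
hierarchy: each pathway becomes a small neural module, and the wiring
between modules mirrors the hierarchy's parent–child structure
(genes → pathways → pathway groups → top categories → output, labelled
levels D, C, B, A, O in the style of KEGG-BRITE).

## The model

Every hierarchy node at levels C, B and A — plus a single output node O —
is a module: a dense stack of three 3-neuron layers (tanh, tanh, identity)
whose first layer reads the concatenation of its children's outputs (one
scalar per gene child, three neurons per module child). Each module also
carries a linear auxiliary classifier head. Training minimises the
**weighted multi-loss**

```
L = Σ_ℓ  w_ℓ · Σ_{m ∈ layer ℓ}  CE_w(head_m, y)   +   λ‖W‖₁ ,
```

where `CE_w` is class-weighted cross-entropy (weights
`n/(K·n_c)` against imbalance), the layer weights default to
`w_C=1.3, w_B=1.2, w_A=1.1, w_O=1.0`, and the L1 penalty uses 0.1 on the
module-input weight blocks and 0.01 elsewhere (biases exempt). Layers join
the objective **progressively** — C from epoch 1, B from 2, A from 4, O
from 6 — and are fully frozen before their inclusion epoch. Evaluation uses
stratified ten-fold cross-validation (per split: 1 test fold, 2 random
validation folds, 7 training folds; the checkpoint with the lowest
validation loss is kept), so every sample is an unseen test prediction
exactly once.

Explanations use **epsilon-rule layer-wise relevance propagation**: the raw
output score of a class is redistributed backwards through every linear
layer via `R_j = Σ_k a_j w_jk / (z_k + ε·sign(z_k)) · R_k`, summing over
fan-out, down to the gene inputs. Per-sample relevance is normalised by the
absolute sum within each level, pooled over all cross-validation test
predictions, and a node is called a **biomarker of exceptional relevance**
when its median normalised relevance exceeds the mean + standard deviation
of the pooled values of its level (and is positive).

## Worked example

Simulate a 60-gene cohort with 6 planted discriminative genes
(3σ mean shift, 60 + 60 samples), cross-validate, and explain:

```bash
xmodnn simulate --spec spec.yaml --seed 11 --out data     # spec: 60 genes, 8 C, 3 B, 2 A
xmodnn crossval --nodes data/nodes.tsv --edges data/edges.tsv \
    --expression data/expression.tsv --labels data/labels.tsv \
    --config cfg.yaml --k 10 --seed 11 --out cv           # cfg: max_epochs 20, batch 16
xmodnn explain --run-dir cv --expression data/expression.tsv --out explain
```

prints

```
pooled balanced accuracy: 0.9833
pooled MCC: 0.9667
flagged 5 nodes; outputs in explain
```

and `explain/biomarkers.tsv` contains

```
node_id  level  median_relevance  threshold  mode
g29      D      0.1000            0.0762     pooled_level
g35      D      0.2137            0.0762     pooled_level
g37      D      0.0872            0.0762     pooled_level
g46      D      0.1785            0.0762     pooled_level
g56      D      0.1117            0.0762     pooled_level
```

All five flagged genes are planted markers (`data/truth.json` lists
`g08 g29 g35 g37 g46 g56`): the pipeline recovers the planted signal with
no false positives at near-perfect pooled classification. `explain/` also
holds per-sample and global relevance tables and SIF/CSV/GraphML exports of
the relevance network for Cytoscape-style viewers.

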