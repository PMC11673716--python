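"""Epsilon-rule layer-wise relevance propagation through the modular network.

A single prediction's class score (raw O-head score of the start class,
pre-softmax) is redistributed backwards through the module DAG to the gene
inputs.  At every linear layer with input a, weights w and pre-activation
z_k = sum_j a_j w_jk (+ b_k), relevance flows as

    R_j = sum_k  a_j w_jk / (z_k + eps * sign(z_k)) * R_k,

with sign(0) treated as +1.  Nonlinearities pass relevance through
unchanged; bias relevance is absorbed, so conservation (sum of gene
relevance equals the seeded score) is exact only with eps = 0 and no biases.
At fan-out nodes (a module feeding several parents) relevance arriving from
all parents is summed.  Auxiliary heads of non-O modules feed nothing
forward and never carry relevance.

A module's scalar relevance is the sum over its last-internal-layer neurons.
Per-level normalisation divides every value by the absolute sum of its level
so per-sample maps are comparable across cross-validation models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import FunctionalHierarchy, LEVELS
from .network import ForwardResult, ModularNetwork, forward

DEFAULT_EPSILON = 1e-6


@dataclass
class RelevanceMap:
    sample_id: str
    start_class: int
    epsilon: float
    node_relevance: dict[str, float]  # gene and module ids, signed
    neuron_relevance: dict[str, np.ndarray]  # module id -> last-layer neurons


def _sign(z: np.ndarray) -> np.ndarray:
    s = np.sign(z)
    s[s == 0] = 1.0
    return s


def lrp_linear_epsilon(
    activations: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None,
    upper_relevance: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Redistribute relevance through one linear layer (epsilon rule)."""
    a = np.asarray(activations, dtype=float)
    w = np.asarray(weights, dtype=float)
    r = np.asarray(upper_relevance, dtype=float)
    z = a @ w
    if bias is not None:
        z = z + bias
    denom = z + epsilon * _sign(z)
    # dead output (z == 0 with eps == 0) passes on no relevance
    factor = np.divide(r, denom, out=np.zeros_like(denom, dtype=float),
                       where=denom != 0)
    return a * (w @ factor)


def lrp_explain(
    net: ModularNetwork,
    x: np.ndarray,
    start_class: int,
    epsilon: float = DEFAULT_EPSILON,
    sample_id: str = "",
    result: ForwardResult | None = None,
) -> RelevanceMap:
    """Propagate one sample's class score back to genes and modules."""
    x = np.asarray(x, dtype=float).ravel()
    if result is None:
        result = forward(net, x)
    h = net.hierarchy
    spec = net.spec
    if not (0 <= start_class < spec.n_classes):
        raise ValueError(f"start_class {start_class} out of range")
    n_layers = len(spec.layer_widths)
    last = spec.layer_widths[-1]
    out_id = h.output_id

    # relevance arriving at each module's output (last internal layer)
    r_out: dict[str, np.ndarray] = {m: np.zeros(last) for m in net.module_order}
    gene_rel = {g: 0.0 for g in net.gene_order}
    gene_col = {g: i for i, g in enumerate(net.gene_order)}

    # seed: raw head score of the start class, pushed through the head column
    p_o = net.modules[out_id]
    a_last_o = result.post[out_id][-1][0]
    score = float(result.head_outputs[out_id][0, start_class])
    r_out[out_id] = lrp_linear_epsilon(
        a_last_o,
        p_o.W_head[:, [start_class]],
        None if p_o.b_head is None else p_o.b_head[[start_class]],
        np.array([score]),
        epsilon,
    )

    neuron_rel: dict[str, np.ndarray] = {}
    for mid in reversed(net.module_order):  # parents before children
        p = net.modules[mid]
        r = r_out[mid]
        neuron_rel[mid] = r.copy()
        for l in range(n_layers - 1, -1, -1):
            a_in = (result.inputs[mid] if l == 0 else result.post[mid][l - 1])[0]
            r = lrp_linear_epsilon(a_in, p.W[l], p.b[l], r, epsilon)
        col = 0
        for child, kind in net.inbound[mid]:
            width = 1 if kind == "gene" else last
            piece = r[col:col + width]
            if kind == "gene":
                gene_rel[child] += float(piece[0])
            else:
                r_out[child] = r_out[child] + piece
            col += width

    node_rel = dict(gene_rel)
    for mid in net.module_order:
        node_rel[mid] = float(neuron_rel[mid].sum())
    return RelevanceMap(sample_id, start_class, epsilon, node_rel, neuron_rel)


def module_relevance(rmap: RelevanceMap, net: ModularNetwork) -> dict[str, float]:
    """Scalar relevance per module: sum over its last-layer neurons."""
    return {mid: float(rmap.neuron_relevance[mid].sum())
            for mid in net.module_order}


def normalize_layerwise(
    values: dict[str, float],
    layer_of: dict[str, str],
) -> dict[str, float]:
    """Divide each value by the absolute sum of its level.

    After normalisation the absolute values within each nonzero level sum to
    one; signs and within-level ratios are preserved.  All-zero levels are
    left as zeros.
    """
    sums = {lv: 0.0 for lv in LEVELS}
    for nid, v in values.items():
        sums[layer_of[nid]] += abs(v)
    out = {}
    for nid, v in values.items():
        s = sums[layer_of[nid]]
        out[nid] = v / s if s > 0 else 0.0
    return out


def normalized_relevance(rmap: RelevanceMap, h: FunctionalHierarchy) -> dict[str, float]:
    layer_of = {nid: h.level_of(nid) for nid in rmap.node_relevance}
    return normalize_layerwise(rmap.node_relevance, layer_of)


@dataclass
class AggregatedRelevance:
    """Cohort-level statistics of normalised relevance per node."""

    table: pd.DataFrame  # index node_id; median, mean, std, n; per-class medians
    per_class: dict[str, pd.DataFrame]
    n_predictions: int

    def median(self, node_id: str) -> float:
        return float(self.table.loc[node_id, "median"])


def aggregate_global(
    maps: list[dict[str, float]],
    h: FunctionalHierarchy,
    classes_of_maps: list[str] | None = None,
) -> AggregatedRelevance:
    """Median/mean/std of normalised relevance across pooled predictions."""
    if not maps:
        raise ValueError("need at least one prediction")
    df = pd.DataFrame(maps)  # rows = predictions, cols = node ids
    stats = pd.DataFrame(
        {"level": [h.level_of(n) for n in df.columns],
         "median": df.median(axis=0),
         "mean": df.mean(axis=0),
         "std": df.std(axis=0, ddof=1) if len(df) > 1 else 0.0,
         "n": len(df)}
    )
    per_class: dict[str, pd.DataFrame] = {}
    if classes_of_maps is not None:
        cls = pd.Series(classes_of_maps)
        for c in sorted(cls.unique()):
            sub = df[cls.values == c]
            per_class[c] = pd.DataFrame(
                {"median": sub.median(axis=0), "mean": sub.mean(axis=0),
                 "std": sub.std(axis=0, ddof=1) if len(sub) > 1 else 0.0,
                 "n": len(sub)}
            )
    return AggregatedRelevance(stats, per_class, len(df))


def pooled_values(maps: list[dict[str, float]], h: FunctionalHierarchy,
                  level: str) -> np.ndarray:
    """All (node, prediction) normalised relevance values at one level."""
    nodes = [n for n in maps[0] if h.level_of(n) == level]
    return np.array([[m[n] for n in nodes] for m in maps]).ravel()
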