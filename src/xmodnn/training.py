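"""Weighted multi-loss progressive training.

Every module owns an auxiliary classifier head; each head's class-weighted
cross-entropy is scaled by a per-level loss weight (defaults C:1.3, B:1.2,
A:1.1, O:1.0) and the scaled losses are aggregated into one objective.
Module layers join the objective progressively (defaults: C from epoch 1,
B from 2, A from 4, O from 6; epochs are 1-indexed); a layer that has not
joined is fully frozen — its parameters receive no gradient from any term,
including the L1 penalty.

L1 penalties: 0.1 on first-internal-layer weight blocks (the module-input
layers), 0.01 on every other weight; biases are exempt.

Gradients are computed by explicit reverse-mode differentiation over the
module DAG — the modules are tiny dense stacks, so this is a page of NumPy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import LabelVector
from .hierarchy import FunctionalHierarchy, MODULE_LEVELS
from .network import ForwardResult, ModularNetwork, ModuleParams, forward

log = logging.getLogger(__name__)

DEFAULT_LOSS_WEIGHTS = {"C": 1.3, "B": 1.2, "A": 1.1, "O": 1.0}
DEFAULT_INCLUSION_EPOCHS = {"C": 1, "B": 2, "A": 4, "O": 6}


@dataclass
class TrainingConfig:
    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 30
    loss_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_WEIGHTS))
    inclusion_epochs: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INCLUSION_EPOCHS))
    l1_all: float = 0.01
    l1_input_layer: float = 0.1
    class_weight_mode: str = "automatic"  # automatic | manual
    manual_class_weights: dict[str, float] | None = None
    optimizer_name: str = "adam"  # adam | sgd
    layer_reduce: str = "sum"  # sum | mean over modules within a level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates and sizes must be positive")
        eps = [self.inclusion_epochs[l] for l in MODULE_LEVELS]
        if any(b < a for a, b in zip(eps, eps[1:])):
            raise ValueError("inclusion epochs must be non-decreasing C<=B<=A<=O")
        if self.layer_reduce not in ("sum", "mean"):
            raise ValueError("layer_reduce must be 'sum' or 'mean'")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError("optimizer_name must be 'adam' or 'sgd'")


def class_weights(labels: LabelVector) -> dict[str, float]:
    """Balanced class weights: w_c = n_total / (n_classes * n_c)."""
    counts = labels.counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    n, k = len(labels), len(counts)
    for c, nc in counts.items():
        if nc == 0:
            raise ValueError(f"class {c!r} has zero samples")
    return {c: n / (k * nc) for c, nc in counts.items()}


def resolve_class_weights(labels: LabelVector, cfg: TrainingConfig) -> np.ndarray:
    """Class-weight vector aligned with ``labels.classes``."""
    if cfg.class_weight_mode == "manual":
        if cfg.manual_class_weights is None:
            raise ValueError("manual class weights requested but none given")
        return np.array([cfg.manual_class_weights[c] for c in labels.classes])
    w = class_weights(labels)
    return np.array([w[c] for c in labels.classes])


def _log_softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=-1, keepdims=True)
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def weighted_cross_entropy(head_scores: np.ndarray, y, w) -> float:
    """Mean over samples of -w_y * log softmax(scores)_y (nats)."""
    scores = np.atleast_2d(np.asarray(head_scores, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    w = np.asarray(w, dtype=float)
    lsm = _log_softmax(scores)
    return float(np.mean(-w[y] * lsm[np.arange(len(y)), y]))


def active_layers(epoch: int, cfg: TrainingConfig) -> set[str]:
    """Module levels participating in the objective at a (1-indexed) epoch."""
    if epoch < 1:
        raise ValueError("epochs are 1-indexed")
    return {l for l in MODULE_LEVELS if epoch >= cfg.inclusion_epochs[l]}


def module_losses(result: ForwardResult, h: FunctionalHierarchy,
                  y: np.ndarray, w: np.ndarray) -> dict[str, float]:
    return {
        mid: weighted_cross_entropy(result.head_outputs[mid], y, w)
        for mid in h.module_order
    }


def multi_loss(losses: dict[str, float], h: FunctionalHierarchy,
               cfg: TrainingConfig, epoch: int,
               levels: set[str] | None = None) -> float:
    """Weighted multi-loss over the active module layers."""
    levels = active_layers(epoch, cfg) if levels is None else levels
    total = 0.0
    for lv in MODULE_LEVELS:
        if lv not in levels:
            continue
        mids = h.ids_at(lv)
        s = sum(losses[m] for m in mids)
        if cfg.layer_reduce == "mean" and mids:
            s /= len(mids)
        total += cfg.loss_weights[lv] * s
    return total


def l1_penalty(net: ModularNetwork, cfg: TrainingConfig,
               levels: set[str] | None = None) -> float:
    """L1 on weights (not biases): 0.1 x first-layer blocks, 0.01 x the rest."""
    total = 0.0
    for mid in net.module_order:
        if levels is not None and net.hierarchy.level_of(mid) not in levels:
            continue
        p = net.modules[mid]
        total += cfg.l1_input_layer * np.abs(p.W[0]).sum()
        for wmat in p.W[1:]:
            total += cfg.l1_all * np.abs(wmat).sum()
        total += cfg.l1_all * np.abs(p.W_head).sum()
    return float(total)


def objective(net: ModularNetwork, x: np.ndarray, y: np.ndarray,
              w: np.ndarray, cfg: TrainingConfig, epoch: int) -> float:
    """multi_loss + l1_penalty restricted to the active layers (for tests)."""
    res = forward(net, x)
    levels = active_layers(epoch, cfg)
    losses = module_losses(res, net.hierarchy, y, w)
    return multi_loss(losses, net.hierarchy, cfg, epoch) + l1_penalty(net, cfg, levels)


# ---------------------------------------------------------------------------
# reverse-mode gradients over the module DAG


def _backward(net: ModularNetwork, res: ForwardResult, y: np.ndarray,
              w: np.ndarray, cfg: TrainingConfig,
              levels: set[str]) -> dict[str, dict[str, np.ndarray]]:
    """Gradient of multi_loss + l1_penalty w.r.t. every active-module array.

    Inactive modules sit above all active ones in the DAG, so no gradient
    path reaches them; they are simply skipped.
    """
    h = net.hierarchy
    n = len(y)
    rows = np.arange(n)
    active = [m for m in net.module_order if h.level_of(m) in levels]
    level_count = {lv: len(h.ids_at(lv)) for lv in MODULE_LEVELS}

    grads: dict[str, dict[str, np.ndarray]] = {}
    d_out: dict[str, np.ndarray] = {}  # grad w.r.t. module output A_last
    for mid in reversed(active):
        p = net.modules[mid]
        lv = h.level_of(mid)
        scale = cfg.loss_weights[lv]
        if cfg.layer_reduce == "mean":
            scale /= level_count[lv]

        # head: d(mean_i -w_y log softmax)/dH = w_y (softmax - onehot) / n
        scores = res.head_outputs[mid]
        s = scores - scores.max(axis=1, keepdims=True)
        probs = np.exp(s)
        probs /= probs.sum(axis=1, keepdims=True)
        dH = probs.copy()
        dH[rows, y] -= 1.0
        dH *= (w[y] / n)[:, None]
        dH *= scale

        a_last = res.post[mid][-1]
        g = {"W_head": a_last.T @ dH + cfg.l1_all * np.sign(p.W_head)}
        if p.b_head is not None:
            g["b_head"] = dH.sum(axis=0)

        dA = d_out.get(mid, 0.0) + dH @ p.W_head.T
        n_layers = len(p.W)
        for l in range(n_layers - 1, -1, -1):
            dZ = dA if l == n_layers - 1 else dA * (1.0 - res.post[mid][l] ** 2)
            a_in = res.inputs[mid] if l == 0 else res.post[mid][l - 1]
            l1 = cfg.l1_input_layer if l == 0 else cfg.l1_all
            g[f"W{l}"] = a_in.T @ dZ + l1 * np.sign(p.W[l])
            if p.b[l] is not None:
                g[f"b{l}"] = dZ.sum(axis=0)
            dA = dZ @ p.W[l].T
        grads[mid] = g

        # distribute input gradient onto module children
        col = 0
        last = net.spec.layer_widths[-1]
        for child, kind in net.inbound[mid]:
            width = 1 if kind == "gene" else last
            if kind == "module":
                piece = dA[:, col:col + width]
                d_out[child] = d_out.get(child, 0.0) + piece
            col += width
    return grads


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[tuple[str, str], np.ndarray] = {}
        self.v: dict[tuple[str, str], np.ndarray] = {}
        self.t: dict[tuple[str, str], int] = {}

    def step(self, key: tuple[str, str], param: np.ndarray, grad: np.ndarray) -> None:
        m = self.m.setdefault(key, np.zeros_like(param))
        v = self.v.setdefault(key, np.zeros_like(param))
        t = self.t.get(key, 0) + 1
        self.t[key] = t
        m *= self.b1
        m += (1 - self.b1) * grad
        v *= self.b2
        v += (1 - self.b2) * grad * grad
        mhat = m / (1 - self.b1 ** t)
        vhat = v / (1 - self.b2 ** t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, key, param, grad) -> None:
        param -= self.lr * grad


def _apply_grads(net: ModularNetwork, grads, opt) -> None:
    for mid, g in grads.items():
        p = net.modules[mid]
        for l in range(len(p.W)):
            opt.step((mid, f"W{l}"), p.W[l], g[f"W{l}"])
            if p.b[l] is not None and f"b{l}" in g:
                opt.step((mid, f"b{l}"), p.b[l], g[f"b{l}"])
        opt.step((mid, "W_head"), p.W_head, g["W_head"])
        if p.b_head is not None and "b_head" in g:
            opt.step((mid, "b_head"), p.b_head, g["b_head"])


@dataclass
class Checkpoint:
    epoch: int
    val_loss: float
    params: dict[str, ModuleParams]


def select_best(checkpoints: list[Checkpoint]) -> Checkpoint:
    """Checkpoint with the lowest validation loss; ties go to the earliest epoch."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    return min(checkpoints, key=lambda c: (c.val_loss, c.epoch))


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    from sklearn.metrics import f1_score

    return float(f1_score(y_true, y_pred, labels=np.arange(n_classes),
                          average="macro", zero_division=0))


def train(
    net: ModularNetwork,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainingConfig,
    class_weight_vec: np.ndarray,
    checkpoint_sink: list[Checkpoint] | None = None,
) -> tuple[ModularNetwork, pd.DataFrame]:
    """Mini-batch optimisation of the progressive weighted multi-loss.

    Returns the best network (lowest validation multi-loss over all layers,
    penalty excluded) and a per-epoch history.  Deterministic for a fixed
    config seed under single-threaded execution.

    The validation loss used for selection always sums every module layer,
    regardless of the inclusion schedule, so values are comparable across
    epochs.
    """
    x_tr, y_tr = train_data
    x_val, y_val = val_data
    w = np.asarray(class_weight_vec, dtype=float)
    h = net.hierarchy
    rng = np.random.default_rng(cfg.seed)
    opt = (_Adam(cfg.learning_rate) if cfg.optimizer_name == "adam"
           else _SGD(cfg.learning_rate))
    all_levels = set(MODULE_LEVELS)
    out_id = h.output_id

    checkpoints: list[Checkpoint] = []
    records = []
    for epoch in range(1, cfg.max_epochs + 1):
        levels = active_layers(epoch, cfg)
        order = rng.permutation(len(y_tr))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            res = forward(net, x_tr[idx])
            grads = _backward(net, res, y_tr[idx], w, cfg, levels)
            _apply_grads(net, grads, opt)

        res_tr = forward(net, x_tr)
        losses_tr = module_losses(res_tr, h, y_tr, w)
        per_layer = {
            lv: sum(losses_tr[m] for m in h.ids_at(lv)) for lv in MODULE_LEVELS
        }
        train_total = multi_loss(losses_tr, h, cfg, epoch) + l1_penalty(net, cfg, levels)
        if not np.isfinite(train_total):
            bad = [m for m, v in losses_tr.items() if not np.isfinite(v)]
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}; offending modules: {bad}"
            )

        res_val = forward(net, x_val)
        losses_val = module_losses(res_val, h, y_val, w)
        val_loss = multi_loss(losses_val, h, cfg, epoch, levels=all_levels)
        val_pred = res_val.head_outputs[out_id].argmax(axis=1)
        val_f1 = _macro_f1(y_val, val_pred, net.spec.n_classes)

        checkpoints.append(Checkpoint(epoch, val_loss, net.copy_params()))
        if checkpoint_sink is not None:
            checkpoint_sink.append(checkpoints[-1])
        records.append(
            {"epoch": epoch,
             **{f"train_loss_{lv}": per_layer[lv] for lv in MODULE_LEVELS},
             "train_total": train_total,
             "val_loss": val_loss,
             "val_f1": val_f1,
             "active_layers": "".join(lv for lv in MODULE_LEVELS if lv in levels)}
        )
        log.debug("epoch %d: train %.4f val %.4f f1 %.3f",
                  epoch, train_total, val_loss, val_f1)

    best = select_best(checkpoints)
    net.set_params(best.params)
    history = pd.DataFrame.from_records(records)
    history.attrs["best_epoch"] = best.epoch
    return net, history
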