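"""Stratified ten-fold cross-validation harness.

Each class is shuffled and dealt into k chunks of near-equal size
(ceil(n_c/k) for the first n_c mod k folds, floor for the rest, larger
chunks to the lowest-index folds); fold f is the union of chunk f over
classes, so every fold matches the cohort's label distribution to within
one sample per class.  Per split, one fold is the test set, two randomly
drawn folds form the validation set and the rest train the model; over the
k splits every sample is an unseen test prediction exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from .expression import ExpressionMatrix, LabelVector, mean_center
from .hierarchy import FunctionalHierarchy
from .network import ModularNetwork, ModuleSpec, build_network, predict_proba
from .training import TrainingConfig, resolve_class_weights, train

log = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict[str, int]  # sample id -> fold index 1..k

    def members(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]

    def sizes(self) -> list[int]:
        counts = [0] * self.k
        for f in self.fold_of.values():
            counts[f - 1] += 1
        return counts


def stratified_folds(labels: LabelVector, k: int, seed: int) -> FoldAssignment:
    """Label-stratified partition into k folds (1-indexed)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds n={len(labels)} samples")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for cls in labels.classes:
        ids = [s for s, l in zip(labels.sample_ids, labels.labels) if l == cls]
        if len(ids) < k:
            log.warning("class %r has %d samples (< k=%d); some folds lack it",
                        cls, len(ids), k)
        perm = rng.permutation(len(ids))
        n_c = len(ids)
        base, extra = divmod(n_c, k)
        pos = 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            for j in perm[pos:pos + size]:
                fold_of[ids[j]] = f + 1
            pos += size
    return FoldAssignment(k, fold_of)


@dataclass
class SplitRoles:
    test_fold: int
    validation_folds: tuple[int, int]
    training_folds: tuple[int, ...]


def assign_roles(folds: FoldAssignment, test_fold: int, seed: int) -> SplitRoles:
    """Pick 2 validation folds at random among the non-test folds."""
    if folds.k < 4:
        raise ValueError("need k >= 4 to reserve a test fold and 2 validation folds")
    if not 1 <= test_fold <= folds.k:
        raise ValueError(f"test fold {test_fold} out of range 1..{folds.k}")
    rng = np.random.default_rng(seed)
    others = [f for f in range(1, folds.k + 1) if f != test_fold]
    val = tuple(sorted(rng.choice(others, size=2, replace=False).tolist()))
    train_f = tuple(f for f in others if f not in val)
    return SplitRoles(test_fold, val, train_f)


@dataclass
class MetricsReport:
    precision: dict[str, float]
    recall: dict[str, float]
    f1_macro: float
    balanced_accuracy: float
    mcc: float
    confusion: np.ndarray
    classes: list[str]

    def as_dict(self) -> dict[str, float]:
        d = {"f1_macro": self.f1_macro,
             "balanced_accuracy": self.balanced_accuracy,
             "mcc": self.mcc}
        for c in self.classes:
            d[f"precision_{c}"] = self.precision[c]
            d[f"recall_{c}"] = self.recall[c]
        return d


def compute_metrics(y_true, y_pred, classes: list[str]) -> MetricsReport:
    """Precision/recall per class, macro F1, balanced accuracy, MCC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    missing = set(classes) - set(y_true.tolist())
    if missing:
        log.warning("classes absent from y_true: %s; their recall reported as 0",
                    sorted(missing))
    prec = precision_score(y_true, y_pred, labels=classes, average=None,
                           zero_division=0)
    rec = recall_score(y_true, y_pred, labels=classes, average=None,
                       zero_division=0)
    return MetricsReport(
        precision={c: float(p) for c, p in zip(classes, prec)},
        recall={c: float(r) for c, r in zip(classes, rec)},
        f1_macro=float(f1_score(y_true, y_pred, labels=classes, average="macro",
                                zero_division=0)),
        balanced_accuracy=float(np.mean(rec)),
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        classes=list(classes),
    )


@dataclass
class SplitResult:
    roles: SplitRoles
    net: ModularNetwork
    history: pd.DataFrame
    center_means: np.ndarray
    test_sample_ids: list[str]
    test_true: list[str]
    test_pred: list[str]
    test_proba: np.ndarray
    metrics: MetricsReport


@dataclass
class CrossvalResult:
    folds: FoldAssignment
    splits: list[SplitResult]
    predictions: pd.DataFrame  # pooled test predictions, one row per sample
    per_split_metrics: pd.DataFrame
    summary: pd.DataFrame  # median/mean/std/min/max per metric
    pooled_metrics: MetricsReport
    classes: list[str]


def run_crossval(
    expression: ExpressionMatrix,
    labels: LabelVector,
    hierarchy: FunctionalHierarchy,
    module_spec: ModuleSpec | None = None,
    training_cfg: TrainingConfig | None = None,
    k: int = 10,
    seed: int = 0,
    center: str = "train_only",
) -> CrossvalResult:
    """Train one model per split and pool the unseen test predictions.

    ``center``: 'train_only' (default) computes per-gene centering means on
    the training folds and re-applies them to validation/test folds; 'global'
    centers the full matrix once before splitting; 'none' skips centering.
    """
    if center not in ("train_only", "global", "none"):
        raise ValueError("center must be 'train_only', 'global' or 'none'")
    spec = module_spec or ModuleSpec()
    cfg = training_cfg or TrainingConfig()
    if spec.n_classes != len(labels.classes):
        spec = ModuleSpec(layer_widths=list(spec.layer_widths),
                          activation=spec.activation, input_bias=spec.input_bias,
                          head_bias=spec.head_bias, n_classes=len(labels.classes))

    x = expression.subset_genes(hierarchy.gene_order)
    if center == "global":
        x, _ = mean_center(x)
    sample_col = {s: i for i, s in enumerate(x.sample_ids)}
    data = x.values.T  # samples x genes
    y_idx = labels.as_indices()
    sample_y = {s: yi for s, yi in zip(labels.sample_ids, y_idx)}

    folds = stratified_folds(labels, k, seed)
    w = resolve_class_weights(labels, cfg)

    splits: list[SplitResult] = []
    for test_fold in range(1, k + 1):
        roles = assign_roles(folds, test_fold, seed + test_fold)
        tr_ids = sorted(s for s, f in folds.fold_of.items() if f in roles.training_folds)
        va_ids = sorted(s for s, f in folds.fold_of.items() if f in roles.validation_folds)
        te_ids = sorted(s for s, f in folds.fold_of.items() if f == test_fold)

        rows_tr = [sample_col[s] for s in tr_ids]
        x_tr = data[rows_tr]
        if center == "train_only":
            means = x_tr.mean(axis=0)
        else:
            means = np.zeros(data.shape[1])
        x_tr = x_tr - means
        x_va = data[[sample_col[s] for s in va_ids]] - means
        x_te = data[[sample_col[s] for s in te_ids]] - means
        y_tr = np.array([sample_y[s] for s in tr_ids])
        y_va = np.array([sample_y[s] for s in va_ids])
        y_te = np.array([sample_y[s] for s in te_ids])

        net = build_network(hierarchy, spec, seed=seed + 1000 * test_fold)
        split_cfg = TrainingConfig(**{**cfg.__dict__, "seed": cfg.seed + test_fold})
        net, history = train(net, (x_tr, y_tr), (x_va, y_va), split_cfg, w)

        proba = predict_proba(net, x_te)
        pred_idx = proba.argmax(axis=1)
        pred = [labels.classes[i] for i in pred_idx]
        true = [labels.classes[i] for i in y_te]
        metrics = compute_metrics(true, pred, labels.classes)
        splits.append(SplitResult(roles, net, history, means, te_ids, true, pred,
                                  proba, metrics))
        log.info("split %d/%d: balanced accuracy %.3f",
                 test_fold, k, metrics.balanced_accuracy)

    rows = []
    for sp in splits:
        for i, s in enumerate(sp.test_sample_ids):
            row = {"sample_id": s, "fold": sp.roles.test_fold,
                   "true": sp.test_true[i], "predicted": sp.test_pred[i]}
            for j, c in enumerate(labels.classes):
                row[f"prob_{c}"] = sp.test_proba[i, j]
            rows.append(row)
    predictions = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)

    per_split = pd.DataFrame(
        [sp.metrics.as_dict() for sp in splits],
        index=pd.Index(range(1, k + 1), name="test_fold"),
    )
    summary = per_split.agg(["median", "mean", "std", "min", "max"])
    pooled = compute_metrics(predictions["true"], predictions["predicted"],
                             labels.classes)
    return CrossvalResult(folds, splits, predictions, per_split, summary,
                          pooled, list(labels.classes))
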