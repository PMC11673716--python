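"""End-to-end explanation pipeline: crossval models -> LRP -> biomarkers.

Each cross-validation split explains its own unseen test samples with the
model trained for that split (re-using the split's centering statistics);
per-sample maps are level-normalised and pooled across all splits into the
global explanation, from which the biomarker threshold is derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .biomarker import BiomarkerSet, threshold_biomarkers
from .crossval import CrossvalResult
from .expression import ExpressionMatrix
from .hierarchy import FunctionalHierarchy
from .relevance import (AggregatedRelevance, aggregate_global, lrp_explain,
                        normalized_relevance, DEFAULT_EPSILON)

log = logging.getLogger(__name__)


@dataclass
class ExplanationResult:
    per_sample: pd.DataFrame  # sample_id, node_id, level, relevance (normalised)
    maps: list[dict[str, float]]
    map_classes: list[str]  # start class of each map
    aggregated: AggregatedRelevance
    biomarkers: BiomarkerSet


def explain_crossval(
    cv: CrossvalResult,
    expression: ExpressionMatrix,
    hierarchy: FunctionalHierarchy,
    epsilon: float = DEFAULT_EPSILON,
    start_class: str = "predicted",  # predicted | true | a class label
    biomarker_levels: set[str] | None = None,
    threshold_mode: str = "pooled_level",
) -> ExplanationResult:
    """Explain every pooled test prediction and threshold the aggregate."""
    x = expression.subset_genes(hierarchy.gene_order)
    sample_col = {s: i for i, s in enumerate(x.sample_ids)}
    data = x.values.T
    class_index = {c: i for i, c in enumerate(cv.classes)}

    maps: list[dict[str, float]] = []
    map_classes: list[str] = []
    rows = []
    for sp in cv.splits:
        for i, sid in enumerate(sp.test_sample_ids):
            if start_class == "predicted":
                cls = sp.test_pred[i]
            elif start_class == "true":
                cls = sp.test_true[i]
            else:
                cls = start_class
            xi = data[sample_col[sid]] - sp.center_means
            rmap = lrp_explain(sp.net, xi, class_index[cls], epsilon,
                               sample_id=sid)
            normed = normalized_relevance(rmap, hierarchy)
            maps.append(normed)
            map_classes.append(cls)
            rows.extend(
                {"sample_id": sid, "node_id": nid,
                 "level": hierarchy.level_of(nid), "relevance": v}
                for nid, v in normed.items()
            )

    agg = aggregate_global(maps, hierarchy, classes_of_maps=map_classes)
    bset = threshold_biomarkers(agg, maps, hierarchy,
                                level_filter=biomarker_levels,
                                mode=threshold_mode)
    per_sample = pd.DataFrame(rows, columns=["sample_id", "node_id", "level",
                                             "relevance"])
    log.info("explained %d predictions; %d nodes flagged",
             len(maps), len(bset.flagged))
    return ExplanationResult(per_sample, maps, map_classes, agg, bset)


def write_relevance_tables(res: ExplanationResult, hierarchy: FunctionalHierarchy,
                           per_sample_path, global_path) -> None:
    res.per_sample.to_csv(per_sample_path, sep="\t", index=False)
    tab = res.aggregated.table.copy()
    tab.insert(0, "node_id", tab.index)
    tab[["node_id", "level", "median", "mean", "std", "n"]].to_csv(
        global_path, sep="\t", index=False)
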