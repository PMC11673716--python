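"""Biomarker thresholding and relevance-network export.

A node counts as a biomarker of exceptional relevance when its median
normalised relevance across all pooled test predictions strictly exceeds a
threshold of mean + standard deviation of the pooled relevance values, and
is positive.  By default the threshold pool is all (node, prediction) values
within the node's level; a per-node variant is available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .hierarchy import FunctionalHierarchy, LEVELS
from .relevance import AggregatedRelevance, pooled_values


@dataclass
class BiomarkerSet:
    thresholds: dict[str, float]  # level -> tau (or node -> tau in per_node mode)
    flagged: dict[str, str]  # node id -> level
    medians: dict[str, float]
    mode: str
    level_filter: tuple[str, ...]

    def ids(self) -> set[str]:
        return set(self.flagged)

    def at_level(self, level: str) -> set[str]:
        return {n for n, lv in self.flagged.items() if lv == level}


def threshold_biomarkers(
    agg: AggregatedRelevance,
    maps: list[dict[str, float]],
    h: FunctionalHierarchy,
    level_filter: set[str] | None = None,
    mode: str = "pooled_level",
) -> BiomarkerSet:
    """Flag nodes whose median relevance exceeds mean + std of pooled values.

    ``mode='pooled_level'`` (default): tau per level from all pooled
    (node, prediction) values of that level.  ``mode='per_node'``: tau per
    node from its own prediction values; the node is flagged when its median
    also exceeds the level's mean of medians.
    """
    levels = tuple(lv for lv in LEVELS if lv != "O"
                   and (level_filter is None or lv in level_filter))
    if mode not in ("pooled_level", "per_node"):
        raise ValueError("mode must be 'pooled_level' or 'per_node'")

    flagged: dict[str, str] = {}
    medians: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    for lv in levels:
        nodes = [n for n in agg.table.index if h.level_of(n) == lv]
        if not nodes:
            continue
        med = {n: float(agg.table.loc[n, "median"]) for n in nodes}
        medians.update(med)
        if mode == "pooled_level":
            pool = pooled_values(maps, h, lv)
            if pool.size < 2:
                raise ValueError(f"fewer than 2 pooled values at level {lv}")
            tau = float(pool.mean() + pool.std(ddof=1))
            thresholds[lv] = tau
            for n in nodes:
                if med[n] > tau and med[n] > 0:
                    flagged[n] = lv
        else:
            grand = float(np.mean(list(med.values())))
            for n in nodes:
                vals = np.array([m[n] for m in maps])
                if vals.size < 2:
                    raise ValueError(f"fewer than 2 values for node {n!r}")
                tau = float(vals.mean() + vals.std(ddof=1))
                thresholds[n] = tau
                if med[n] > tau and med[n] > grand and med[n] > 0:
                    flagged[n] = lv
    return BiomarkerSet(thresholds, flagged, medians, mode, levels)


def write_biomarkers(b: BiomarkerSet, agg: AggregatedRelevance, path) -> None:
    rows = []
    for n, lv in sorted(b.flagged.items()):
        tau = b.thresholds[lv if b.mode == "pooled_level" else n]
        rows.append({"node_id": n, "level": lv, "median_relevance": b.medians[n],
                     "threshold": tau, "mode": b.mode})
    pd.DataFrame(rows, columns=["node_id", "level", "median_relevance",
                                "threshold", "mode"]).to_csv(path, sep="\t",
                                                             index=False)


def export_relevance_network(
    h: FunctionalHierarchy,
    agg: AggregatedRelevance,
    biomarkers: BiomarkerSet,
    out_dir,
    flagged_only: bool = False,
) -> dict[str, Path]:
    """Write SIF, node-attribute CSV and GraphML for graph viewers.

    With ``flagged_only`` the export is restricted to the sub-network induced
    by flagged nodes and their ancestors (plus the O node).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if flagged_only:
        keep = set(biomarkers.ids()) | {h.output_id}
        for n in biomarkers.ids():
            keep |= h.ancestors(n)
    else:
        keep = set(h.nodes)

    edges = [(c, p) for c, p in h.edges() if c in keep and p in keep]
    sif = out_dir / "relevance_network.sif"
    with open(sif, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for c, p in edges:
            wr.writerow([c, "part_of", p])

    def med(n: str) -> float:
        if n in agg.table.index:
            return float(agg.table.loc[n, "median"])
        return float("nan")

    nodes_sorted = sorted(keep)
    attrs = pd.DataFrame(
        {"node_id": nodes_sorted,
         "level": [h.level_of(n) for n in nodes_sorted],
         "median_relevance": [med(n) for n in nodes_sorted],
         "flagged": [n in biomarkers.flagged for n in nodes_sorted]}
    )
    csv_path = out_dir / "relevance_nodes.csv"
    attrs.to_csv(csv_path, index=False)

    g = nx.DiGraph()
    for _, row in attrs.iterrows():
        g.add_node(row["node_id"], level=row["level"],
                   median_relevance=float(row["median_relevance"]),
                   flagged=bool(row["flagged"]))
    g.add_edges_from(edges)
    graphml = out_dir / "relevance_network.graphml"
    nx.write_graphml(g, graphml)
    return {"sif": sif, "csv": csv_path, "graphml": graphml}
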