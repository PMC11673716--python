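"""Functional hierarchy: the leveled DAG that defines the network wiring.

Genes sit at level D; pathways at level C; pathway groups at level B; top
categories at level A; a single output node O closes the hierarchy.  Edges
may only connect adjacent levels (D->C, C->B, B->A, A->O).  A gene or module
may belong to several parents (multi-membership), in which case the network
wiring fans out accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd

LEVELS: tuple[str, ...] = ("D", "C", "B", "A", "O")
MODULE_LEVELS: tuple[str, ...] = ("C", "B", "A", "O")
_LEVEL_INDEX = {lv: i for i, lv in enumerate(LEVELS)}


class HierarchyError(ValueError):
    """Raised when a hierarchy violates a structural invariant."""


@dataclass
class HierarchyNode:
    id: str
    level: str
    name: str = ""
    parents: set[str] = field(default_factory=set)
    children: set[str] = field(default_factory=set)


@dataclass
class FunctionalHierarchy:
    """Validated leveled DAG of :class:`HierarchyNode` objects.

    ``nodes`` maps id -> node.  Gene order (``gene_order``) and module
    evaluation order (``module_order``, children before parents) are
    deterministic: sorted within each level, independent of file order.
    """

    nodes: dict[str, HierarchyNode]
    level_order: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        self.validate()

    # -- views ------------------------------------------------------------
    def ids_at(self, level: str) -> list[str]:
        return sorted(i for i, n in self.nodes.items() if n.level == level)

    @property
    def gene_order(self) -> list[str]:
        return self.ids_at("D")

    @property
    def module_order(self) -> list[str]:
        """Module ids in topological (children-first) order: C, B, A, O."""
        out: list[str] = []
        for lv in MODULE_LEVELS:
            out.extend(self.ids_at(lv))
        return out

    @property
    def output_id(self) -> str:
        return self.ids_at("O")[0]

    def level_of(self, node_id: str) -> str:
        return self.nodes[node_id].level

    def children_sorted(self, node_id: str) -> list[str]:
        return sorted(self.nodes[node_id].children)

    def ancestors(self, node_id: str) -> set[str]:
        """All nodes reachable via parent links (excluding the node itself)."""
        seen: set[str] = set()
        stack = list(self.nodes[node_id].parents)
        while stack:
            p = stack.pop()
            if p not in seen:
                seen.add(p)
                stack.extend(self.nodes[p].parents)
        return seen

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for nid, node in self.nodes.items():
            if node.level not in _LEVEL_INDEX:
                raise HierarchyError(
                    f"node {nid!r}: unknown level {node.level!r}; expected one of {LEVELS}"
                )
            for p in node.parents:
                if p not in self.nodes:
                    raise HierarchyError(f"node {nid!r} has unknown parent {p!r}")
                if _LEVEL_INDEX[self.nodes[p].level] != _LEVEL_INDEX[node.level] + 1:
                    raise HierarchyError(
                        f"edge between non-adjacent levels "
                        f"{node.level}→{self.nodes[p].level} ({nid!r}→{p!r})"
                    )
            for c in node.children:
                if c not in self.nodes or nid not in self.nodes[c].parents:
                    raise HierarchyError(f"inconsistent child link {nid!r}→{c!r}")

        o_nodes = [i for i, n in self.nodes.items() if n.level == "O"]
        if len(o_nodes) != 1:
            raise HierarchyError(
                f"expected exactly one level-O output node, found {len(o_nodes)}"
            )
        if self.nodes[o_nodes[0]].parents:
            raise HierarchyError("the O node must have no parents")

        for nid, node in self.nodes.items():
            if node.level != "O" and not node.parents:
                raise HierarchyError(f"non-O node {nid!r} has no parent")
            if node.level != "D" and not node.children:
                raise HierarchyError(f"non-D node {nid!r} has no children")
            if node.level == "D" and node.children:
                raise HierarchyError(f"level-D node {nid!r} must not have children")

        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):  # levels should preclude this
            raise HierarchyError("hierarchy contains a cycle")

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, level=node.level, name=node.name)
        for nid, node in self.nodes.items():
            for p in node.parents:
                g.add_edge(nid, p)
        return g

    def edges(self) -> list[tuple[str, str]]:
        """Sorted (child_id, parent_id) pairs."""
        return sorted(
            (nid, p) for nid, node in self.nodes.items() for p in node.parents
        )


def _build(nodes: Iterable[tuple[str, str, str]],
           edges: Iterable[tuple[str, str]]) -> FunctionalHierarchy:
    table: dict[str, HierarchyNode] = {}
    for nid, level, name in nodes:
        nid = str(nid)
        if nid in table:
            raise HierarchyError(f"duplicate node id {nid!r}")
        table[nid] = HierarchyNode(id=nid, level=str(level).strip(), name=str(name))
    for child, parent in edges:
        child, parent = str(child), str(parent)
        if child not in table:
            raise HierarchyError(f"edge references unknown child {child!r}")
        if parent not in table:
            raise HierarchyError(f"edge references unknown parent {parent!r}")
        table[child].parents.add(parent)
        table[parent].children.add(child)
    return FunctionalHierarchy(nodes=table)


def load_hierarchy(node_table_path, edge_table_path) -> FunctionalHierarchy:
    """Load a hierarchy from two TSV files.

    ``nodes.tsv`` has columns ``id``, ``level``, ``name`` (header row);
    ``edges.tsv`` has columns ``child_id``, ``parent_id``.  Row order does
    not affect the result.
    """
    nodes = pd.read_csv(node_table_path, sep="\t", dtype=str).fillna("")
    for col in ("id", "level"):
        if col not in nodes.columns:
            raise HierarchyError(f"node table missing column {col!r}")
    if "name" not in nodes.columns:
        nodes["name"] = nodes["id"]
    edges = pd.read_csv(edge_table_path, sep="\t", dtype=str)
    for col in ("child_id", "parent_id"):
        if col not in edges.columns:
            raise HierarchyError(f"edge table missing column {col!r}")
    return _build(
        zip(nodes["id"], nodes["level"], nodes["name"]),
        zip(edges["child_id"], edges["parent_id"]),
    )


def write_hierarchy(h: FunctionalHierarchy, node_table_path, edge_table_path) -> None:
    """Inverse of :func:`load_hierarchy` (TSV dialect)."""
    ids = sorted(h.nodes)
    pd.DataFrame(
        {"id": ids,
         "level": [h.nodes[i].level for i in ids],
         "name": [h.nodes[i].name for i in ids]}
    ).to_csv(node_table_path, sep="\t", index=False)
    ed = h.edges()
    pd.DataFrame(
        {"child_id": [c for c, _ in ed], "parent_id": [p for _, p in ed]}
    ).to_csv(edge_table_path, sep="\t", index=False)


def load_hierarchy_json(path) -> FunctionalHierarchy:
    """Single-file JSON alternative: {"nodes": [...], "edges": [...]}."""
    with open(path) as fh:
        doc = json.load(fh)
    return _build(
        ((n["id"], n["level"], n.get("name", n["id"])) for n in doc["nodes"]),
        ((e["child_id"], e["parent_id"]) for e in doc["edges"]),
    )


def write_hierarchy_json(h: FunctionalHierarchy, path) -> None:
    doc = {
        "nodes": [
            {"id": i, "level": h.nodes[i].level, "name": h.nodes[i].name}
            for i in sorted(h.nodes)
        ],
        "edges": [{"child_id": c, "parent_id": p} for c, p in h.edges()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def prune_to_genes(h: FunctionalHierarchy, measured_genes: set[str],
                   exclude_ids: set[str] | None = None) -> FunctionalHierarchy:
    """Restrict the hierarchy to the intersection with ``measured_genes``.

    Level-D nodes outside ``measured_genes`` are removed; non-D nodes left
    without children are removed, cascading upward.  The O node is never
    removed.  ``exclude_ids`` optionally drops whole user-named branches
    (e.g. catch-all categories) before pruning.
    """
    if not measured_genes:
        raise HierarchyError("measured_genes must be non-empty")
    exclude_ids = exclude_ids or set()

    kept = {
        nid for nid, node in h.nodes.items()
        if nid not in exclude_ids and (node.level != "D" or nid in measured_genes)
    }
    if not any(h.nodes[i].level == "D" for i in kept):
        raise HierarchyError("no measured genes in hierarchy")

    # cascade upward level by level: drop non-D, non-O nodes with no kept child
    for lv in ("C", "B", "A"):
        for nid in h.ids_at(lv):
            if nid in kept and not (h.nodes[nid].children & kept):
                kept.discard(nid)
    # drop kept nodes that lost every parent (cannot happen for O)
    changed = True
    while changed:
        changed = False
        for nid in list(kept):
            node = h.nodes[nid]
            if node.level != "O" and not (node.parents & kept):
                kept.discard(nid)
                changed = True
            elif node.level not in ("D", "O") and not (node.children & kept):
                kept.discard(nid)
                changed = True

    new_nodes = {
        nid: HierarchyNode(
            id=nid,
            level=h.nodes[nid].level,
            name=h.nodes[nid].name,
            parents=h.nodes[nid].parents & kept,
            children=h.nodes[nid].children & kept,
        )
        for nid in kept
    }
    return FunctionalHierarchy(nodes=new_nodes)


def hierarchy_stats(h: FunctionalHierarchy) -> dict:
    """Node counts per level, edge count, and fan-out distribution."""
    counts = {lv: len(h.ids_at(lv)) for lv in LEVELS}
    fan_out = {
        lv: sorted(len(h.nodes[i].children) for i in h.ids_at(lv))
        for lv in MODULE_LEVELS
    }
    return {
        "nodes_per_level": counts,
        "n_nodes": len(h.nodes),
        "n_edges": len(h.edges()),
        "fan_out": fan_out,
    }
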