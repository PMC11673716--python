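"""Synthetic hierarchies and two-class expression data with known ground truth.

The generator emulates the statistical shape of log-scale transcriptomic
classification tasks: Gaussian background expression, a small set of planted
discriminative genes shifted by a chosen effect size in one class, and
optional class imbalance.  It does not emulate probe-level artefacts or
count overdispersion — inputs are post-normalisation log values by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .expression import (ExpressionMatrix, LabelVector, write_expression,
                         write_labels)
from .hierarchy import FunctionalHierarchy, HierarchyNode, write_hierarchy


@dataclass
class SyntheticSpec:
    n_genes: int = 200
    n_c: int = 20
    n_b: int = 6
    n_a: int = 2
    membership_fanout: float = 1.0  # mean parents per gene / C / B node
    n_samples: tuple[int, int] = (100, 100)  # per class (allows imbalance)
    n_planted: int = 10
    effect_size: float = 3.0  # mean shift in units of noise sigma
    noise_sigma: float = 1.0
    ar1_rho: float = 0.0  # optional within-pathway background correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_c, self.n_b, self.n_a) < 1:
            raise ValueError("counts must be positive")
        if self.membership_fanout < 1.0:
            raise ValueError("membership_fanout must be >= 1")
        if self.n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


@dataclass
class GroundTruth:
    planted_genes: list[str]
    planted_modules: dict[str, list[str]]  # level -> ancestor module ids
    classes: tuple[str, str] = ("class1", "class2")

    def to_json(self) -> str:
        return json.dumps(
            {"planted_genes": self.planted_genes,
             "planted_modules": self.planted_modules,
             "classes": list(self.classes)}, indent=1)


def _assign(rng: np.random.Generator, children: list[str], parents: list[str],
            fanout: float) -> list[tuple[str, str]]:
    """Each child gets one round-robin parent plus Poisson(fanout-1) extras;
    a parent left childless (fewer children than parents) adopts one."""
    edges = []
    for i, c in enumerate(children):
        chosen = {parents[i % len(parents)]}
        extra = rng.poisson(fanout - 1.0)
        if extra:
            pool = [p for p in parents if p not in chosen]
            rng.shuffle(pool)
            chosen.update(pool[:extra])
        edges.extend((c, p) for p in sorted(chosen))
    used = {p for _, p in edges}
    for p in parents:
        if p not in used:
            edges.append((str(rng.choice(children)), p))
    return edges


def make_hierarchy(spec: SyntheticSpec) -> tuple[FunctionalHierarchy, GroundTruth]:
    """Deterministic per seed.  Returns the hierarchy and which C/B/A modules
    contain planted genes (ancestor annotation)."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    genes = [f"g{str(i + 1).zfill(width)}" for i in range(spec.n_genes)]
    cs = [f"c{i + 1}" for i in range(spec.n_c)]
    bs = [f"b{i + 1}" for i in range(spec.n_b)]
    as_ = [f"a{i + 1}" for i in range(spec.n_a)]

    nodes = {g: HierarchyNode(g, "D", g) for g in genes}
    nodes.update({c: HierarchyNode(c, "C", f"pathway {c}") for c in cs})
    nodes.update({b: HierarchyNode(b, "B", f"group {b}") for b in bs})
    nodes.update({a: HierarchyNode(a, "A", f"category {a}") for a in as_})
    nodes["O"] = HierarchyNode("O", "O", "output")

    edges = (_assign(rng, genes, cs, spec.membership_fanout)
             + _assign(rng, cs, bs, spec.membership_fanout)
             + _assign(rng, bs, as_, spec.membership_fanout)
             + [(a, "O") for a in as_])
    for c, p in edges:
        nodes[c].parents.add(p)
        nodes[p].children.add(c)
    h = FunctionalHierarchy(nodes=nodes)

    planted = sorted(rng.choice(genes, size=spec.n_planted, replace=False).tolist())
    ancestors: dict[str, set[str]] = {"C": set(), "B": set(), "A": set()}
    for g in planted:
        for anc in h.ancestors(g):
            lv = h.level_of(anc)
            if lv in ancestors:
                ancestors[lv].add(anc)
    truth = GroundTruth(planted, {lv: sorted(v) for lv, v in ancestors.items()})
    return h, truth


def make_expression(
    spec: SyntheticSpec, h: FunctionalHierarchy, truth: GroundTruth,
) -> tuple[ExpressionMatrix, LabelVector]:
    """Background ~ Normal(0, sigma^2) in both classes; planted genes get a
    +effect_size*sigma mean shift in the second class."""
    rng = np.random.default_rng(spec.seed + 1)
    genes = h.gene_order
    n1, n2 = spec.n_samples
    n = n1 + n2
    x = rng.normal(0.0, spec.noise_sigma, size=(len(genes), n))

    if spec.ar1_rho > 0:  # AR(1) mixing of background within each C pathway
        rho = spec.ar1_rho
        gene_row = {g: i for i, g in enumerate(genes)}
        for c in h.ids_at("C"):
            rows = [gene_row[g] for g in h.children_sorted(c)]
            for prev, cur in zip(rows, rows[1:]):
                x[cur] = rho * x[prev] + np.sqrt(1 - rho ** 2) * x[cur]

    gene_row = {g: i for i, g in enumerate(genes)}
    delta = spec.effect_size * spec.noise_sigma
    for g in truth.planted_genes:
        x[gene_row[g], n1:] += delta

    width = len(str(n))
    sample_ids = [f"s{str(i + 1).zfill(width)}" for i in range(n)]
    labels = [truth.classes[0]] * n1 + [truth.classes[1]] * n2
    return (ExpressionMatrix(list(genes), sample_ids, x),
            LabelVector(sample_ids, labels))


def simulate(spec: SyntheticSpec) -> tuple[
        FunctionalHierarchy, ExpressionMatrix, LabelVector, GroundTruth]:
    h, truth = make_hierarchy(spec)
    x, y = make_expression(spec, h, truth)
    return h, x, y, truth


def write_dataset(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Emit nodes.tsv, edges.tsv, expression.tsv, labels.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, x, y, truth = simulate(spec)
    paths = {k: out / f"{k}" for k in
             ("nodes.tsv", "edges.tsv", "expression.tsv", "labels.tsv",
              "truth.json")}
    write_hierarchy(h, paths["nodes.tsv"], paths["edges.tsv"])
    write_expression(x, paths["expression.tsv"])
    write_labels(y, paths["labels.tsv"])
    paths["truth.json"].write_text(truth.to_json())
    return paths
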