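"""Expression-matrix and label I/O, duplicate-ID aggregation, mean-centering.

Inputs are assumed already on a log scale (e.g. log2 microarray intensity or
log2(TPM+1)); no normalisation of raw counts happens here.  Missing values
are a load error, not something to impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids),
                                self.values[rows, :])


@dataclass
class LabelVector:
    """One class label per sample; classes are the sorted distinct labels."""

    sample_ids: list[str]
    labels: list[str]
    classes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.classes = sorted(set(self.labels))

    def __len__(self) -> int:
        return len(self.sample_ids)

    def as_indices(self) -> np.ndarray:
        """Labels encoded as integer class indices (order of ``classes``)."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.classes}


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and one column per sample.

    Any non-numeric or missing cell is an error naming its row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-numeric cell {df[col].iloc[i]!r} at gene {df.index[i]!r}, "
                f"sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy()
    if df.index.isna().any() or df.index.duplicated().any():
        raise ValueError(f"missing or duplicate gene id in first column of {path}")
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                            values)


def write_expression(x: ExpressionMatrix, path) -> None:
    x.to_frame().rename_axis("gene_id").to_csv(path, sep="\t",
                                               float_format="%.12g")


def read_labels(path) -> LabelVector:
    """Read a `sample_id<TAB>label` TSV with header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"label table missing column {col!r}")
    if df["label"].isna().any():
        raise ValueError("missing label")
    return LabelVector(list(df["sample_id"]), list(df["label"]))


def write_labels(y: LabelVector, path) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "label": y.labels}).to_csv(
        path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"probe map missing column {col!r}")
    return df


def aggregate_duplicates(x: ExpressionMatrix, mapping: pd.DataFrame) -> ExpressionMatrix:
    """Collapse probe rows to genes by the arithmetic mean.

    ``mapping`` has columns ``probe_id`` and ``gene_id``.  Probes absent from
    the mapping are dropped (count logged).  A probe mapped to several genes
    contributes its row to each of them (fan-out, logged).
    """
    probe_rows = {p: i for i, p in enumerate(x.gene_ids)}
    mapped = mapping[mapping["probe_id"].isin(probe_rows)]
    unmapped = len(x.gene_ids) - mapped["probe_id"].nunique()
    if unmapped:
        log.info("aggregate_duplicates: dropping %d unmapped probes", unmapped)
    fanout = mapped["probe_id"].value_counts()
    n_fan = int((fanout > 1).sum())
    if n_fan:
        log.info("aggregate_duplicates: %d probes map to multiple genes", n_fan)

    gene_ids = sorted(mapped["gene_id"].unique())
    values = np.empty((len(gene_ids), len(x.sample_ids)))
    by_gene = mapped.groupby("gene_id")["probe_id"]
    for i, g in enumerate(gene_ids):
        rows = [probe_rows[p] for p in by_gene.get_group(g)]
        values[i] = x.values[rows, :].mean(axis=0)
    return ExpressionMatrix(gene_ids, list(x.sample_ids), values)


def mean_center(
    x: ExpressionMatrix,
    means: np.ndarray | None = None,
    axis: str = "gene",
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Subtract per-gene (default) or per-sample means.

    Returns the centered matrix and the means that were subtracted.  Inside
    cross-validation, call once on the training split and re-apply the
    returned ``means`` to validation/test splits so that held-out data never
    contributes to the statistics.
    """
    if axis not in ("gene", "sample"):
        raise ValueError("axis must be 'gene' or 'sample'")
    if axis == "gene":
        if means is None:
            means = x.values.mean(axis=1)
        centered = x.values - np.asarray(means)[:, None]
    else:
        if means is None:
            means = x.values.mean(axis=0)
        centered = x.values - np.asarray(means)[None, :]
    return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), centered), np.asarray(means)
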