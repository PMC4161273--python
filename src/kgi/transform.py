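"""Gene-set aggregation: expression matrix → knowledge matrix.

Each gene set that survives the size filter becomes one feature: for every
sample, the expression values of the set's *measured* member genes (those
present in the expression matrix) are summed and divided by the number of
measured members, i.e. the feature is the mean member expression.  Dividing
by the member count removes the bias a raw sum would carry toward large
sets.  The size filter keeps only sets with strictly more than
``min_measured`` measured genes (default 10), since aggregates over very
small sets are noisy.

Feature identifiers are ``<source>:<set-id>`` with characters that are
structural in model text (whitespace, parentheses, commas, ``*``) replaced
by underscores, so any knowledge feature can appear verbatim inside an
evolved model.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FormatError, GeneSetCollection

_SANITIZE_RE = re.compile(r"[\s(),*]+")

#: default gene-set size filter: keep sets with > 10 measured genes
DEFAULT_MIN_MEASURED = 10


def sanitize_feature_id(source_name: str, set_id: str) -> str:
    return _SANITIZE_RE.sub("_", f"{source_name}:{set_id}")


@dataclass
class KnowledgeMatrix:
    """Samples × gene-set features, with the membership that produced them."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    membership: dict[str, list[str]] = field(default_factory=dict)
    source_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicated feature ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def columns(self) -> dict[str, np.ndarray]:
        """Feature name → column view, the shape model evaluation expects."""
        return {f: self.values[:, j] for j, f in enumerate(self.feature_ids)}

    def subset_samples(self, indices: Sequence[int]) -> "KnowledgeMatrix":
        idx = list(indices)
        return KnowledgeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx, :].copy(),
            self.membership,
            self.source_name,
        )

    def select_features(self, feature_ids: Sequence[str]) -> "KnowledgeMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature(s): {', '.join(missing)}")
        cols = [pos[f] for f in feature_ids]
        return KnowledgeMatrix(
            list(self.sample_ids),
            list(feature_ids),
            self.values[:, cols].copy(),
            {f: self.membership.get(f, []) for f in feature_ids},
            self.source_name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


def concat_features(
    matrices: Sequence[KnowledgeMatrix], source_name: str = "COMBINED"
) -> KnowledgeMatrix:
    """Column-concatenate sample-aligned knowledge matrices."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.sample_ids != first.sample_ids:
            raise FormatError("matrices are not sample-aligned")
    feature_ids: list[str] = []
    membership: dict[str, list[str]] = {}
    for m in matrices:
        feature_ids.extend(m.feature_ids)
        membership.update(m.membership)
    values = np.hstack([m.values for m in matrices])
    return KnowledgeMatrix(
        list(first.sample_ids), feature_ids, values, membership, source_name
    )


def filter_gene_sets(
    collection: GeneSetCollection,
    expr: ExpressionMatrix,
    min_measured: int = DEFAULT_MIN_MEASURED,
) -> GeneSetCollection:
    """Keep sets with strictly more than ``min_measured`` measured genes.

    Member lists in the returned collection are restricted to measured
    genes (those present in ``expr.gene_ids``).  An empty result is valid.
    """
    if min_measured < 0:
        raise ValueError("min_measured must be >= 0")
    measured = set(expr.gene_ids)
    kept: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for set_id, genes in collection.sets.items():
        present = [g for g in genes if g in measured]
        if len(present) > min_measured:
            kept[set_id] = present
            if set_id in collection.descriptions:
                descriptions[set_id] = collection.descriptions[set_id]
    return GeneSetCollection(collection.source_name, kept, descriptions)


def build_knowledge_matrix(
    expr: ExpressionMatrix, collection: GeneSetCollection
) -> KnowledgeMatrix:
    """Aggregate expression into one mean-valued feature per gene set.

    Every member gene must be measured: run :func:`filter_gene_sets` first.
    Sample order is preserved; genes may belong to many sets.
    """
    col_of = {g: j for j, g in enumerate(expr.gene_ids)}
    feature_ids: list[str] = []
    membership: dict[str, list[str]] = {}
    cols: list[np.ndarray] = []
    for set_id, genes in collection.sets.items():
        missing = [g for g in genes if g not in col_of]
        if missing:
            raise FormatError(
                f"set {set_id!r} references unmeasured gene(s) "
                f"{', '.join(missing[:5])}; apply filter_gene_sets first"
            )
        fid = sanitize_feature_id(collection.source_name, set_id)
        if fid in membership:
            raise FormatError(f"feature id collision after sanitizing: {fid!r}")
        idx = [col_of[g] for g in genes]
        cols.append(expr.values[:, idx].mean(axis=1))
        feature_ids.append(fid)
        membership[fid] = list(genes)
    values = (
        np.column_stack(cols) if cols else np.empty((len(expr.sample_ids), 0))
    )
    return KnowledgeMatrix(
        list(expr.sample_ids),
        feature_ids,
        values,
        membership,
        collection.source_name,
    )


def knowledge_matrix_from_expression(
    expr: ExpressionMatrix, source_name: str = "EXPR"
) -> KnowledgeMatrix:
    """Treat each gene as its own feature (the gene-expression baseline)."""
    feature_ids = [sanitize_feature_id(source_name, g) for g in expr.gene_ids]
    if len(set(feature_ids)) != len(feature_ids):
        raise FormatError("gene ids collide after sanitizing")
    membership = {f: [g] for f, g in zip(feature_ids, expr.gene_ids)}
    return KnowledgeMatrix(
        list(expr.sample_ids),
        feature_ids,
        expr.values.copy(),
        membership,
        source_name,
    )


def write_knowledge_matrix(matrix: KnowledgeMatrix, path: str | Path) -> None:
    """TSV matrix plus a ``<path>.membership.json`` sidecar."""
    path = Path(path)
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="sample")
    sidecar = path.with_suffix(path.suffix + ".membership.json")
    sidecar.write_text(
        json.dumps(
            {"source_name": matrix.source_name, "membership": matrix.membership},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )


def read_knowledge_matrix(path: str | Path) -> KnowledgeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".membership.json")
    source_name, membership = "", {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        source_name = meta.get("source_name", "")
        membership = meta.get("membership", {})
    return KnowledgeMatrix(
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
        membership,
        source_name,
    )
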