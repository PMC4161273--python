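"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* expression matrix — TSV, samples in rows by default (flag to flip), header
  row of gene identifiers, first column sample identifiers, no missing
  values;
* gene-set collections — Broad-style GMT (set name, description, member
  genes, tab-separated, one set per line);
* phenotype — two-column TSV mapping sample id to a class label;
* evolved models — human-readable prefix text plus a JSON provenance
  sidecar.

Gene identifiers are matched between GMT files and the expression header by
exact, case-sensitive string comparison; symbol aliasing is an upstream
curation concern, not handled here.  All readers accept LF or CRLF line
endings and UTF-8 with or without a BOM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import NetworkModel, model_from_text, model_to_text

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Samples × genes continuous expression values, no missing entries."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        for kind, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise FormatError(f"duplicated {kind} id(s): {', '.join(dups)}")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def read_expression(
    path: str | Path,
    *,
    samples_in_rows: bool = True,
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Header row holds gene ids and the first column sample ids (the reverse
    when ``samples_in_rows`` is False — TCGA-style matrices come both ways).
    Duplicate identifiers or missing/non-numeric cells are format errors
    naming the offender.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8-sig", newline=None) as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise FormatError(f"{path}: empty file")
        col_ids = header_line.split(delimiter)[1:]
        dups = _find_duplicates(col_ids)
        if dups:
            raise FormatError(f"{path}: duplicated column id(s): {', '.join(dups)}")
        row_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != len(col_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(col_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            row_ids.append(fields[0])
            rows.append(fields[1:])
    dups = _find_duplicates(row_ids)
    if dups:
        raise FormatError(f"{path}: duplicated row id(s): {', '.join(dups)}")
    values = np.empty((len(rows), len(col_ids)), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"{path}: missing/non-finite cell at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r}"
        )
    if not samples_in_rows:
        row_ids, col_ids, values = col_ids, row_ids, values.T.copy()
    return ExpressionMatrix(row_ids, col_ids, values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """A named knowledge source holding named gene sets."""

    source_name: str
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            dups = _find_duplicates(genes)
            if dups:
                raise FormatError(
                    f"set {set_id!r} lists duplicate gene(s): {', '.join(dups)}"
                )

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, source_name: str) -> GeneSetCollection:
    """Read a GMT file (one set per line: name, description, genes...).

    Duplicate genes within a line are dropped with a logged warning; a line
    with fewer than three fields is a format error.  An empty file yields an
    empty (valid) collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8-sig", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            set_id, desc, genes = fields[0], fields[1], fields[2:]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicated set id {set_id!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: set %r lists duplicate genes; deduplicated",
                    path,
                    lineno,
                    set_id,
                )
            sets[set_id] = deduped
            descriptions[set_id] = desc
    return GeneSetCollection(source_name, sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, genes in collection.sets.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# phenotype


@dataclass
class PhenotypeVector:
    """Ordered sample ids with binary labels (1 = case, 0 = control)."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise FormatError("labels must align one-to-one with sample_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise FormatError("labels must be 0/1")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise FormatError(f"duplicated sample id(s): {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def both_classes_present(self) -> bool:
        return 0 < self.n_positive < len(self)

    def subset(self, indices: Sequence[int]) -> "PhenotypeVector":
        idx = list(indices)
        return PhenotypeVector(
            [self.sample_ids[i] for i in idx], self.labels[idx].copy()
        )


def read_phenotype(
    path: str | Path,
    positive_label: str,
    negative_label: Optional[str] = None,
) -> PhenotypeVector:
    """Read a two-column sample→label file and binarize the labels.

    ``positive_label`` maps to 1.  When ``negative_label`` is given any
    other string is an error; otherwise the single remaining label is
    inferred as the control class (two or more distinct non-positive labels
    is an error).  Sample order is preserved.
    """
    path = Path(path)
    samples: list[str] = []
    raw: list[str] = []
    with open(path, "r", encoding="utf-8-sig", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            samples.append(fields[0])
            raw.append(fields[1])
    dups = _find_duplicates(samples)
    if dups:
        raise FormatError(f"{path}: duplicated sample(s): {', '.join(dups)}")
    others = sorted(set(raw) - {positive_label})
    if negative_label is None:
        if len(others) > 1:
            raise FormatError(
                f"{path}: ambiguous control labels {others}; pass negative_label"
            )
    else:
        bad = [o for o in others if o != negative_label]
        if bad:
            culprit = samples[raw.index(bad[0])]
            raise FormatError(
                f"{path}: sample {culprit!r} has unknown label {bad[0]!r}"
            )
    labels = np.array([1 if r == positive_label else 0 for r in raw])
    return PhenotypeVector(samples, labels)


def write_phenotype(
    pheno: PhenotypeVector,
    path: str | Path,
    positive_label: str = "1",
    negative_label: str = "0",
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, lab in zip(pheno.sample_ids, pheno.labels):
            fh.write(f"{sid}\t{positive_label if lab else negative_label}\n")


# ---------------------------------------------------------------------------
# model serialization


@dataclass
class SerializedModel:
    """Model text plus a JSON-serializable provenance record."""

    text: str
    provenance: dict = field(default_factory=dict)


def serialize_model(
    model: NetworkModel, provenance: Optional[dict] = None
) -> SerializedModel:
    return SerializedModel(model_to_text(model), dict(provenance or {}))


def deserialize_model(serialized: SerializedModel | str) -> NetworkModel:
    text = serialized if isinstance(serialized, str) else serialized.text
    return model_from_text(text)


def write_model(serialized: SerializedModel, path: str | Path) -> None:
    """Write the model text to *path* and provenance to ``<path>.json``."""
    path = Path(path)
    path.write_text(serialized.text + "\n", encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(serialized.provenance, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_model(path: str | Path) -> SerializedModel:
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    sidecar = path.with_suffix(path.suffix + ".json")
    provenance = (
        json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.exists() else {}
    )
    model = model_from_text(text)  # validates
    return SerializedModel(model.to_text(), provenance)
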