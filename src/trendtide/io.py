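"""Readers and writers for all external formats.

Abundance matrices are delimited text with a condition header row and gene
IDs in the first column.  Gene lists are plain text, one ID per line.  GO
annotation comes as GMT or as a two-column (gene TAB term) mapping.  Result
tables are exported as CSV, the Sankey/comparison models as JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from trendtide.matrix import AbundanceMatrix

log = logging.getLogger(__name__)

GO_CATEGORIES = ("molecular function", "biological process", "cellular component")

# pinned float formatting so repeated runs produce byte-identical text output
FLOAT_FORMAT = "%.10g"


def _sniff_delimiter(path: Path) -> str:
    """Tab first, then comma."""
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    return ","


def read_abundance(
    path,
    dataset_id: str | None = None,
    delimiter: str | None = None,
    uppercase_ids: bool = False,
) -> AbundanceMatrix:
    """Load an abundance matrix (genes x conditions) from delimited text.

    Genes with any missing or non-numeric cell are dropped and recorded in
    the returned matrix's ``dropped`` field.  Duplicate gene IDs, fewer than
    two condition columns, or an empty file raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty file: {path}") from None
    if df.shape[0] == 0:
        raise ValueError(f"empty file (header only): {path}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: found {df.shape[1]} conditions; need >= 2")
    df.index = df.index.astype(str).str.strip()
    if uppercase_ids:
        df.index = df.index.str.upper()
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene IDs in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    complete = numeric.notna().all(axis=1)
    dropped = tuple(df.index[~complete])
    if dropped:
        log.warning(
            "%s: dropped %d gene(s) with missing/non-numeric cells: %s",
            path, len(dropped), ", ".join(dropped[:10]),
        )
    numeric = numeric.loc[complete]
    if numeric.shape[0] == 0:
        raise ValueError(f"{path}: no gene has a complete numeric profile")
    if dataset_id is None:
        dataset_id = path.stem
    return AbundanceMatrix(dataset_id=dataset_id, data=numeric, state="raw", dropped=dropped)


def write_abundance(matrix: AbundanceMatrix, path, delimiter: str = "\t") -> Path:
    path = Path(path)
    matrix.data.to_csv(path, sep=delimiter, index_label="gene", float_format=FLOAT_FORMAT)
    return path


def read_gene_list(path) -> set[str]:
    """Plain text, one gene ID per line; blank lines ignored, IDs trimmed."""
    path = Path(path)
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


@dataclass
class CustomClustering:
    """A user-supplied pairwise trend comparison.

    Carries, for every intersecting gene, one trend label per dataset plus
    the abundance profiles over the shared conditions.  Labels may be any
    hashable values in the input file; they are mapped to a canonical
    ``0..k-1`` space (sorted original labels) so downstream behavior is
    identical to an internally produced clustering.
    """

    matrix_a: AbundanceMatrix
    matrix_b: AbundanceMatrix
    labels_a: dict[str, int]
    labels_b: dict[str, int]
    label_names: tuple[str, ...]  # canonical index -> original label

    @property
    def k(self) -> int:
        return len(self.label_names)


def read_custom_clustering(path, delimiter: str | None = None) -> CustomClustering:
    """Read a long-format (gene, dataset, condition, value, cluster) file.

    Every gene must appear in exactly two datasets with identical condition
    sets; custom files describe intersecting genes only.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"gene": str, "dataset": str, "cluster": str})
    required = {"gene", "dataset", "condition", "value", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    datasets = sorted(df["dataset"].unique())
    if len(datasets) != 2:
        raise ValueError(f"{path}: expected exactly 2 datasets, found {datasets}")
    ds_a, ds_b = datasets
    per_ds_genes = {ds: set(df.loc[df["dataset"] == ds, "gene"]) for ds in datasets}
    lonely = sorted(per_ds_genes[ds_a] ^ per_ds_genes[ds_b])
    if lonely:
        raise ValueError(f"{path}: genes present in only one dataset: {lonely}")
    per_ds_conds = {ds: set(df.loc[df["dataset"] == ds, "condition"]) for ds in datasets}
    if per_ds_conds[ds_a] != per_ds_conds[ds_b]:
        raise ValueError(f"{path}: inconsistent condition sets between datasets")
    cond_order = list(dict.fromkeys(df["condition"]))  # first-appearance order

    label_names = tuple(sorted(df["cluster"].unique()))
    label_map = {name: i for i, name in enumerate(label_names)}

    matrices, labels = {}, {}
    for ds in datasets:
        sub = df[df["dataset"] == ds]
        wide = sub.pivot(index="gene", columns="condition", values="value")[cond_order]
        if wide.isna().any().any():
            raise ValueError(f"{path}: incomplete profiles in dataset {ds!r}")
        matrices[ds] = AbundanceMatrix(dataset_id=ds, data=wide.astype(float))
        lab = sub.drop_duplicates("gene").set_index("gene")["cluster"]
        labels[ds] = {g: label_map[v] for g, v in lab.items()}
    return CustomClustering(
        matrix_a=matrices[ds_a],
        matrix_b=matrices[ds_b],
        labels_a=labels[ds_a],
        labels_b=labels[ds_b],
        label_names=label_names,
    )


@dataclass(frozen=True)
class Annotation:
    """One GO term and its member genes."""

    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.category not in GO_CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {GO_CATEGORIES}"
            )
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty member set")


def _parse_gmt_description(desc: str) -> tuple[str, str | None]:
    """Split 'name|category' descriptions; bare names get no category."""
    if "|" in desc:
        name, cat = desc.split("|", 1)
        cat = cat.strip().lower().replace("_", " ")
        if cat in GO_CATEGORIES:
            return name.strip(), cat
    return desc.strip(), None


def read_annotation(path, format: str = "gmt", category: str = "biological process") -> list[Annotation]:
    """Read gene->GO-term annotation as GMT or two-column mapping.

    GMT lines are ``term<TAB>description<TAB>gene...``; the description may
    embed a category as ``name|molecular function`` etc., otherwise the
    `category` default applies.  Two-column lines are ``gene<TAB>term``.
    Terms that end up with no members are dropped with a warning.
    """
    path = Path(path)
    records: list[Annotation] = []
    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed GMT line (need >=2 fields)")
                term_id, desc, members = parts[0], parts[1], [g for g in parts[2:] if g.strip()]
                name, cat = _parse_gmt_description(desc)
                if not members:
                    log.warning("%s:%d: term %s has no members; dropped", path, lineno, term_id)
                    continue
                records.append(
                    Annotation(term_id, name or term_id, cat or category, frozenset(members))
                )
    elif format == "two_column":
        groups: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                gene, term = parts[0].strip(), parts[1].strip()
                if not gene or not term:
                    raise ValueError(f"{path}:{lineno}: empty gene or term field")
                groups.setdefault(term, set()).add(gene)
        for term, members in sorted(groups.items()):
            records.append(Annotation(term, term, category, frozenset(members)))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return records


def export_csv(table: pd.DataFrame, path, index: bool = False) -> Path:
    """Write a result table as RFC-4180-style CSV with a pinned float format."""
    path = Path(path)
    table.to_csv(path, index=index, float_format=FLOAT_FORMAT, quoting=csv.QUOTE_MINIMAL,
                 lineterminator="\n")
    return path


def export_json(obj, path) -> Path:
    """Serialize a model (anything with ``to_dict``) or plain dict as JSON."""
    path = Path(path)
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
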