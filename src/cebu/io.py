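"""Readers, writers and alignment for the tabular artifacts.

CSV (comma) for matrices, TSV for pair/GI/prognosis tables, GMT for gene
sets; every reader accepts gzip transparently (pandas infers from the
``.gz`` suffix).  Matrix orientation (genes-in-rows vs cell-lines-in-rows)
is auto-detected from a header token and can be forced.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from cebu.datatypes import AlignedDataset, PairList

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_pair_table",
    "read_gene_sets",
    "align_datasets",
]

#: header token marking a transposed (cell-lines-in-rows) matrix
_TRANSPOSED_TOKEN = "cell_line"


def read_matrix(path: str | Path, kind: str = "dependency",
                orientation: str = "auto") -> pd.DataFrame:
    """Read a gene x cell-line matrix from CSV.

    Parameters
    ----------
    path : str or Path
        CSV file, optionally gzipped.  First column holds row IDs.
    kind : {"dependency", "expression"}
        Expression matrices are checked for non-negativity (log2(TPM+1)).
    orientation : {"auto", "genes_in_rows", "cells_in_rows"}
        With "auto", a first-header token of ``cell_line`` marks a
        transposed file (DepMap releases flip orientation across versions).

    Returns
    -------
    DataFrame with genes as the index and cell lines as columns.
    """
    if kind not in ("dependency", "expression"):
        raise ValueError(f"unknown matrix kind: {kind!r}")
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty matrix: {path}")
    index_name = (df.index.name or "").strip().lower()
    if orientation == "auto":
        orientation = ("cells_in_rows" if index_name == _TRANSPOSED_TOKEN
                       else "genes_in_rows")
    if orientation == "cells_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")

    for axis, label in ((df.index, "gene"), (df.columns, "cell line")):
        if axis.has_duplicates:
            dupes = axis[axis.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {label} IDs in {path}: {dupes[:5]}")

    df = df.apply(pd.to_numeric, errors="coerce")
    bad_rows = df.index[df.isna().all(axis=1)]
    if len(bad_rows) == len(df):
        raise ValueError(f"no numeric data parsed from {path}")
    if len(bad_rows):
        logger.warning("%s: %d rows with no parseable numeric values",
                       path, len(bad_rows))
    if kind == "expression" and (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}; "
                         "expected log2(TPM+1) >= 0")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix CSV that :func:`read_matrix` round-trips bit-exactly."""
    out = df.copy()
    out.index.name = "gene"
    # repr-precision floats survive the text round trip exactly
    out.to_csv(path, float_format="%.17g")


def read_annotation(path: str | Path) -> pd.Series:
    """Read the cell-line -> tissue annotation CSV.

    Requires columns ``cell_line`` and ``tissue_type``; returns a Series
    indexed by cell line.
    """
    df = pd.read_csv(path)
    required = {"cell_line", "tissue_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation requires columns {sorted(required)}")
    if df["cell_line"].duplicated().any():
        raise ValueError("duplicate cell lines in annotation")
    return df.set_index("cell_line")["tissue_type"]


_PAIR_COLUMNS = {
    "duplicated": ["gene_a", "gene_b"],
    "annotation": ["gene_a", "gene_b"],
    "ppi": ["gene_a", "gene_b"],
    "gi": ["cell_line", "gene_a", "gene_b", "score"],
}


def read_pair_table(path: str | Path, kind: str = "annotation") -> PairList:
    """Read a TSV pair list (duplicated / annotation / ppi / gi).

    GI tables must carry ``cell_line`` and ``score`` columns; annotation
    kinds are stored symmetrically so that (a, b) and (b, a) are one pair.
    """
    if kind not in _PAIR_COLUMNS:
        raise ValueError(f"unknown pair-table kind: {kind!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PAIR_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if kind == "gi":
        df["score"] = pd.to_numeric(df["score"])
    return PairList(df, kind=kind)


def write_pair_table(pairs: PairList, path: str | Path) -> None:
    pairs.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, ``name<TAB>desc<TAB>genes...``."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    sets: dict[str, set[str]] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *genes = fields
            sets[name] = {g for g in genes if g}
    return sets


def align_datasets(dependency: pd.DataFrame, expression: pd.DataFrame,
                   annotation: pd.Series) -> AlignedDataset:
    """Align the panels on their shared cell lines.

    Cell lines are the intersection of the three sources, ordered
    lexicographically for determinism.  Dependency genes with any missing
    value over the retained cell lines are dropped (and counted); missing
    expression values are floored to 0, the log2(TPM+1) minimum.
    """
    cells = sorted(set(dependency.columns) & set(expression.columns)
                   & set(annotation.index))
    if not cells:
        raise ValueError("no cell lines shared by dependency, expression "
                         "and annotation")
    dep = dependency[cells]
    keep = dep.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("alignment dropped %d dependency genes with missing "
                    "scores", n_dropped)
    dep = dep.loc[keep]
    expr = expression[cells]
    if expr.isna().any().any():
        logger.warning("missing expression values floored to 0")
        expr = expr.fillna(0.0)
    ds = AlignedDataset(dep, expr, annotation.loc[cells])
    ds.n_dropped_dependency_genes = n_dropped
    return ds
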