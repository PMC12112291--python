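"""Readers and writers for the formats the tool touches.

Supported formats:

* MatrixMarket coordinate counts (.mtx) with one-column text sidecars holding
  gene and cell identifiers;
* dense CSV/TSV counts with a header row and an ID column;
* GMT gene-set collections (name, description, member genes, tab-separated);
* two-column ``cell_id<TAB>condition`` label tables.

Counts are always returned cells x genes regardless of on-disk orientation
(CellRanger-style MTX is genes x cells, hence the ``genes_as_rows`` flag).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, GeneSetCollection, ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "filter_genesets",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


def _read_ids(path: Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    return ids


def read_counts(
    path: str | os.PathLike,
    format: str = "mtx",
    genes_as_rows: bool = True,
    genes_file: str | os.PathLike | None = None,
    cells_file: str | os.PathLike | None = None,
) -> CountMatrix:
    """Read a UMI count matrix into cells x genes orientation.

    For ``format="mtx"``, ``genes_file`` and ``cells_file`` are one-column
    text sidecars (defaulting to ``genes.txt`` / ``cells.txt`` next to the
    matrix). For ``format="csv"`` the first column holds row IDs and the
    header row holds column IDs; the delimiter is sniffed from the suffix
    (``.tsv``/``.txt`` -> tab).
    """
    path = Path(path)
    if format == "mtx":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.txt"
        cells_file = Path(cells_file) if cells_file else path.parent / "cells.txt"
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        gene_ids = _read_ids(genes_file)
        cell_ids = _read_ids(cells_file)
        if genes_as_rows:
            n_genes_disk, n_cells_disk = mat.shape
        else:
            n_cells_disk, n_genes_disk = mat.shape
        if len(gene_ids) != n_genes_disk:
            raise FormatError(
                f"{genes_file}: {len(gene_ids)} gene IDs for a matrix with "
                f"{n_genes_disk} gene axis entries"
            )
        if len(cell_ids) != n_cells_disk:
            raise FormatError(
                f"{cells_file}: {len(cell_ids)} cell IDs for a matrix with "
                f"{n_cells_disk} cell axis entries"
            )
        if genes_as_rows:
            mat = mat.T
        return CountMatrix(mat, cell_ids, gene_ids)
    if format == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if genes_as_rows:
            df = df.T
        return CountMatrix(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))
    raise ValueError(f"unknown format {format!r}")


def write_counts(
    cm: CountMatrix,
    path: str | os.PathLike,
    format: str = "mtx",
    genes_as_rows: bool = True,
) -> None:
    """Write counts; the inverse of :func:`read_counts` (bit-exact round trip)."""
    path = Path(path)
    if format == "mtx":
        mat = cm.counts.T if genes_as_rows else cm.counts
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat))
        # mmwrite appends .mtx if missing; normalise so sidecars sit next to it
        with open(path.parent / "genes.txt", "w") as fh:
            fh.write("\n".join(cm.gene_ids) + ("\n" if cm.gene_ids else ""))
        with open(path.parent / "cells.txt", "w") as fh:
            fh.write("\n".join(cm.cell_ids) + ("\n" if cm.cell_ids else ""))
        return
    if format == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids)
        if genes_as_rows:
            df = df.T
        df.to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format {format!r}")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    The description field is discarded; duplicate genes within a line are
    dropped keeping the first occurrence; duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return GeneSetCollection(sets=sets)


def write_gmt(col: GeneSetCollection, path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in col.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column ``cell_id<TAB>condition`` table (no header)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            if fields[0] in labels:
                raise FormatError(f"{path}: line {lineno}: duplicate cell ID {fields[0]!r}")
            labels[fields[0]] = fields[1]
    return labels


def write_labels(labels: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for cell, cond in labels.items():
            fh.write(f"{cell}\t{cond}\n")


def filter_genesets(
    col: GeneSetCollection,
    measured_genes: Sequence[str],
    min_size: int = 40,
    max_size: int = 1000,
) -> GeneSetCollection:
    """Intersect each set with the measured genes, then apply the size filter.

    Sets are retained iff ``min_size <= size <= max_size`` after intersection
    (bounds inclusive: sets strictly smaller than ``min_size`` or strictly
    larger than ``max_size`` are discarded). Intersection preserves the
    within-set gene order. Idempotent.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    measured = set(measured_genes)
    out: dict[str, list[str]] = {}
    for name, genes in col.sets.items():
        kept = [g for g in genes if g in measured]
        if min_size <= len(kept) <= max_size:
            out[name] = kept
    truth = None
    if col.truth_label is not None:
        truth = {k: v for k, v in col.truth_label.items() if k in out}
    return GeneSetCollection(sets=out, truth_label=truth)
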