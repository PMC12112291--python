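"""In-memory containers for UMI count data and gene-set collections.

The package convention is cells x genes: rows are cells, columns are genes.
Counts are non-negative integers (UMIs); a two-level per-cell condition label
may be attached for differential analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["CountMatrix", "GeneSetCollection"]


class ValidationError(ValueError):
    """Raised when data violates a container invariant."""


@dataclass
class CountMatrix:
    """A cells x genes matrix of UMI counts with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer array, shape (n_cells, n_genes).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    condition
        Optional per-cell label with exactly two levels; attached via
        :meth:`with_condition` or at construction.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        n, p = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell IDs for {n} matrix rows"
            )
        if len(self.gene_ids) != p:
            raise ValidationError(
                f"{len(self.gene_ids)} gene IDs for {p} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell IDs")
        if len(set(self.gene_ids)) != p:
            raise ValidationError("duplicate gene IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            rounded = np.rint(as_float)
            if not np.array_equal(as_float, rounded):
                bad = np.argwhere(as_float != rounded)[0]
                raise ValidationError(
                    f"non-integer count at cell {self.cell_ids[bad[0]]}, "
                    f"gene {self.gene_ids[bad[1]]}"
                )
            self.counts = rounded.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at cell {self.cell_ids[bad[0]]}, "
                f"gene {self.gene_ids[bad[1]]}"
            )
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
            if self.condition.shape != (n,):
                raise ValidationError("condition must have one label per cell")
            levels = set(self.condition.tolist())
            if len(levels) != 2:
                raise ValidationError(
                    f"condition must have exactly two levels, got {sorted(map(str, levels))}"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices for ``genes``; raises if any gene is unmeasured."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            self.counts[:, idx], list(self.cell_ids), [self.gene_ids[i] for i in idx],
            None if self.condition is None else self.condition.copy(),
        )

    def subset_cells(self, rows: np.ndarray) -> "CountMatrix":
        rows = np.asarray(rows)
        return CountMatrix(
            self.counts[rows],
            [self.cell_ids[i] for i in rows],
            list(self.gene_ids),
            None if self.condition is None else self.condition[rows],
        )

    def with_condition(self, labels: Mapping[str, str]) -> "CountMatrix":
        """Attach a two-level condition label keyed by cell ID."""
        missing = [c for c in self.cell_ids if c not in labels]
        if missing:
            raise ValidationError(f"no condition label for cell(s): {missing[:5]}")
        cond = np.array([labels[c] for c in self.cell_ids], dtype=object)
        return replace(self, condition=cond)

    def condition_levels(self) -> tuple[str, str]:
        if self.condition is None:
            raise ValidationError("no condition labels attached")
        levels = sorted(set(self.condition.tolist()))
        return levels[0], levels[1]


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with optional benchmark truth labels.

    ``truth_label`` maps set name to one of {"positive", "negative",
    "ambiguous"} and is only used by the benchmark module.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    truth_label: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes within set {name!r}")
        if self.truth_label is not None:
            bad = set(self.truth_label.values()) - {"positive", "negative", "ambiguous"}
            if bad:
                raise ValidationError(f"invalid truth labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterable[str]:
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
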