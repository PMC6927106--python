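"""Index-aligned matrix containers shared across the package.

Everything downstream of I/O works on plain numpy arrays wrapped with an
:class:`EntityIndex` so that rows/columns can always be traced back to protein
and term identifiers.  Ordering is the lexicographic sort of the identifiers,
which makes every derived matrix reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EntityIndex",
    "AnnotationMatrix",
    "MaskMatrix",
    "SimilarityNetwork",
]

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class EntityIndex:
    """Bijective mapping between entity identifiers and 0-based positions.

    Identifiers are stored in lexicographic order so the index (and every
    matrix built on top of it) is stable across runs and input row orders.
    """

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(sorted(self.ids)))
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate identifiers in index")
        object.__setattr__(
            self, "_position", {name: i for i, name in enumerate(self.ids)}
        )

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "EntityIndex":
        return cls(ids=tuple(set(ids)))

    def position(self, name: str) -> int:
        return self._position[name]

    def __contains__(self, name: str) -> bool:
        return name in self._position

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


@dataclass
class AnnotationMatrix:
    """Binary protein x term matrix Y with its row/column indexes.

    Rows are proteins, columns are ontology terms; ``values[i, j] == 1`` iff
    protein ``i`` is annotated with term ``j``.  Rows are expected to be
    hierarchy-closed with respect to the ontology used to build them.
    """

    values: np.ndarray
    row_index: EntityIndex
    col_index: EntityIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError("matrix shape does not match indexes")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError("annotation matrix entries must be binary")

    @property
    def n_proteins(self) -> int:
        return len(self.row_index)

    @property
    def n_terms(self) -> int:
        return len(self.col_index)

    @property
    def nnz(self) -> int:
        return int(self.values.sum())

    def sparsity(self) -> float:
        """Fraction of nonzero cells, nnz / (N_p * N_h)."""
        return self.nnz / (self.n_proteins * self.n_terms)

    def pairs(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return {
            (self.row_index.ids[i], self.col_index.ids[j])
            for i, j in zip(rows.tolist(), cols.tolist())
        }


@dataclass
class MaskMatrix:
    """Binary loss mask W: cells with W == 0 are excluded from the fit."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError("mask entries must be binary")

    @property
    def n_heldout(self) -> int:
        return int((self.values == 0).sum())


@dataclass
class SimilarityNetwork:
    """Symmetric non-negative weighted graph over proteins or terms.

    Invariants (enforced on construction): symmetry within 1e-12, elementwise
    non-negativity and a zero diagonal (self-loops carry no information for a
    graph Laplacian).
    """

    weights: np.ndarray
    index: EntityIndex
    kind: str = "protein"  # {"protein", "term"}

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.index)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match index")
        if self.kind not in ("protein", "term"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if (self.weights < 0).any():
            raise ValueError("network weights must be non-negative")
        if np.abs(np.diagonal(self.weights)).max(initial=0.0) > 0:
            raise ValueError("network diagonal must be zero")
        if n and np.abs(self.weights - self.weights.T).max() > _SYM_TOL:
            raise ValueError("network weights must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.index)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)
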