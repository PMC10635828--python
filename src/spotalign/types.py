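"""Core in-memory containers shared across the package.

The central object is :class:`ExpressionMatrix`, a dense genes-by-columns
matrix tagged with a normalization layer.  Columns are cells for a
single-cell matrix and spots (or replicated sub-spots) for a spatial
matrix.  All containers validate their invariants on construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

LAYERS = ("raw", "cpm", "log2cpm")

CPM_TOTAL = 1_000_000.0


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense nonnegative genes × columns matrix with a layer tag.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_columns)``.
    gene_ids, column_ids
        Unique, ordered identifiers for rows and columns.
    layer
        One of ``"raw"`` (counts), ``"cpm"`` (columns sum to 1e6) or
        ``"log2cpm"`` (log2 of CPM + 1).
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes × columns)")
        ng, nc = self.values.shape
        if ng != len(self.gene_ids):
            raise ValueError(
                f"{ng} rows but {len(self.gene_ids)} gene ids"
            )
        if nc != len(self.column_ids):
            raise ValueError(
                f"{nc} columns but {len(self.column_ids)} column ids"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.column_ids, "column id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.layer in ("raw", "cpm") and np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[r]!r}, "
                f"column {self.column_ids[c]!r}"
            )
        if self.layer == "cpm":
            sums = self.values.sum(axis=0)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], CPM_TOTAL, rtol=1e-6):
                raise ValueError("cpm layer columns must sum to 1e6")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def column_index(self) -> pd.Index:
        return pd.Index(self.column_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index().get_indexer(list(genes))
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not present: {missing[:5]}")
        return replace(
            self, values=self.values[idx, :], gene_ids=[str(g) for g in genes]
        )

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        idx = self.column_index().get_indexer(list(columns))
        if np.any(idx < 0):
            missing = [c for c, i in zip(columns, idx) if i < 0]
            raise KeyError(f"columns not present: {missing[:5]}")
        return replace(
            self, values=self.values[:, idx], column_ids=[str(c) for c in columns]
        )

    def with_layer(self, layer: str) -> "ExpressionMatrix":
        """Return a re-tagged copy (validation re-runs for the new layer)."""
        return replace(self, layer=layer)


@dataclass
class CellAnnotation:
    """cell_id → cell_type mapping."""

    types: dict[str, str]

    def __post_init__(self) -> None:
        if not self.types:
            raise ValueError("empty annotation")
        for cid, ct in self.types.items():
            if not str(ct).strip():
                raise ValueError(f"empty cell type for cell {cid!r}")
        self.types = {str(c): str(t).strip() for c, t in self.types.items()}

    def __len__(self) -> int:
        return len(self.types)

    def __getitem__(self, cell_id: str) -> str:
        return self.types[cell_id]

    def cell_types(self) -> list[str]:
        return sorted(set(self.types.values()))

    def cells_of_type(self, cell_type: str) -> list[str]:
        return [c for c, t in self.types.items() if t == cell_type]

    def census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.types.values():
            out[t] = out.get(t, 0) + 1
        return out


@dataclass
class SpotGeometry:
    """spot_id → planar (x, y) coordinates."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sid, (x, y) in self.coords.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for spot {sid!r}")
        self.coords = {
            str(s): (float(x), float(y)) for s, (x, y) in self.coords.items()
        }

    def __len__(self) -> int:
        return len(self.coords)

    def as_array(self, spot_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.coords[s] for s in spot_ids], dtype=float)


@dataclass
class CellTypeFractions:
    """Global cell-type fractional abundances, summing to one."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        self.fractions = {str(k): float(v) for k, v in self.fractions.items()}
        for k, v in self.fractions.items():
            if v < 0:
                raise ValueError(f"negative fraction for {k!r}: {v}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.fractions)

    def __getitem__(self, cell_type: str) -> float:
        return self.fractions[cell_type]

    def types(self) -> list[str]:
        return sorted(self.fractions)


@dataclass
class MappingRow:
    query_cell_id: str
    assigned_spot_id: str
    sub_spot_index: int
    cell_type: str
    provenance: str  # original | duplicated | generated
    confidence: Optional[float] = None


PROVENANCES = ("original", "duplicated", "generated")


@dataclass
class MappingTable:
    """The cell → sub-spot assignment result, one row per pool cell."""

    rows: list[MappingRow]

    def __post_init__(self) -> None:
        seen_idx: set[int] = set()
        seen_pairs: set[tuple[str, int]] = set()
        for r in self.rows:
            if r.provenance not in PROVENANCES:
                raise ValueError(f"bad provenance {r.provenance!r}")
            if r.sub_spot_index in seen_idx:
                raise ValueError(f"duplicate sub_spot_index {r.sub_spot_index}")
            seen_idx.add(r.sub_spot_index)
            key = (r.query_cell_id, r.sub_spot_index)
            if key in seen_pairs:
                raise ValueError(f"duplicate (cell, sub-spot) pair {key}")
            seen_pairs.add(key)
            if r.confidence is not None and not (0.0 <= r.confidence <= 1.0):
                raise ValueError(f"confidence outside [0,1]: {r.confidence}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_cell_id": [r.query_cell_id for r in self.rows],
                "assigned_spot_id": [r.assigned_spot_id for r in self.rows],
                "sub_spot_index": [r.sub_spot_index for r in self.rows],
                "cell_type": [r.cell_type for r in self.rows],
                "provenance": [r.provenance for r in self.rows],
                "confidence": [r.confidence for r in self.rows],
            }
        )

    def cell_to_spots(self) -> dict[str, set[str]]:
        """Spots each query cell id was assigned to (a cell may appear in
        several rows when it was duplicated)."""
        out: dict[str, set[str]] = {}
        for r in self.rows:
            out.setdefault(r.query_cell_id, set()).add(r.assigned_spot_id)
        return out
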