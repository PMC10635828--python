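"""Resampling of the annotated single-cell matrix to match per-type targets.

The assignment requires exactly as many query cells as sub-spots, with
cell types represented at their target counts.  Two schemes fill a
shortfall (num_sc,k < num_ST,k):

* duplication — keep every real cell of the type, then draw the deficit
  uniformly with replacement from those same cells; appropriate for
  real-data mapping since every mapped profile is a measured cell;
* generation — synthesize the deficit gene-by-gene, each gene's value
  copied from a uniformly chosen cell of the type; used in benchmarking
  so that duplicated cells cannot inflate precision (generated cells
  carry no ground-truth location and are excluded from scoring).

A surplus (num_sc,k >= num_ST,k) is handled identically in both modes:
a uniform draw without replacement.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spot_model import TypeTargets
from .types import CellAnnotation, ExpressionMatrix


@dataclass
class SampledPool:
    """The K query cells matched to the L sub-spots."""

    expr: ExpressionMatrix
    cell_types: list[str]        # per column
    provenance: list[str]        # per column: original|duplicated|generated
    source_cell_ids: list[Optional[str]]  # None for generated columns
    seed: int

    def __post_init__(self) -> None:
        k = self.expr.n_columns
        if not (len(self.cell_types) == len(self.provenance) == len(self.source_cell_ids) == k):
            raise ValueError("per-column metadata length mismatch")

    @property
    def K(self) -> int:
        return self.expr.n_columns

    def census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.cell_types:
            out[t] = out.get(t, 0) + 1
        return out


def _type_rng(master_seed: int, cell_type: str) -> np.random.Generator:
    """One independent, named stream per cell type: adding or removing a
    type never perturbs another type's draws."""
    key = zlib.crc32(cell_type.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def _base_selection(
    cells: list[str], target: int, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Common branch: (kept originals, duplicated draws) before any
    generation step; duplicates empty when target <= available."""
    n = len(cells)
    if n >= target:
        keep = sorted(rng.choice(n, size=target, replace=False).tolist())
        return [cells[i] for i in keep], []
    extra = rng.integers(0, n, size=target - n)
    return list(cells), [cells[i] for i in extra]


def _pool_from_columns(
    sc: ExpressionMatrix,
    columns: list[np.ndarray],
    ids: list[str],
    types: list[str],
    prov: list[str],
    sources: list[Optional[str]],
    seed: int,
) -> SampledPool:
    values = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((sc.n_genes, 0))
    )
    expr = ExpressionMatrix(values, list(sc.gene_ids), ids, layer=sc.layer)
    return SampledPool(expr, types, prov, sources, seed)


def _check_targets(ann: CellAnnotation, targets: TypeTargets) -> None:
    census = ann.census()
    for t, c in targets.targets.items():
        if c > 0 and census.get(t, 0) == 0:
            raise ValueError(
                f"target {c} for cell type {t!r} absent from the scRNA-seq data"
            )


def sample_duplication(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    targets: TypeTargets,
    seed: int,
) -> SampledPool:
    """Duplication scheme: every pooled profile is a measured cell."""
    _check_targets(ann, targets)
    col_of = {c: i for i, c in enumerate(sc.column_ids)}
    columns, ids, types, prov, sources = [], [], [], [], []
    for t in sorted(targets.targets):
        target = targets[t]
        if target == 0:
            continue
        cells = sorted(c for c in ann.cells_of_type(t) if c in col_of)
        if not cells:
            raise ValueError(f"cell type {t!r} has no cells in the matrix")
        rng = _type_rng(seed, t)
        originals, duplicated = _base_selection(cells, target, rng)
        for c in originals:
            columns.append(sc.values[:, col_of[c]])
            ids.append(f"{t}|orig|{c}")
            types.append(t)
            prov.append("original")
            sources.append(c)
        for j, c in enumerate(duplicated):
            columns.append(sc.values[:, col_of[c]])
            ids.append(f"{t}|dup{j}|{c}")
            types.append(t)
            prov.append("duplicated")
            sources.append(c)
    return _pool_from_columns(sc, columns, ids, types, prov, sources, seed)


def sample_generation(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    targets: TypeTargets,
    seed: int,
) -> SampledPool:
    """Generation scheme: the shortfall is synthesized gene-wise.

    Each generated cell draws, independently per gene, the value of a
    uniformly chosen real cell of the same type, so every generated
    value lies in the type's observed support.
    """
    _check_targets(ann, targets)
    col_of = {c: i for i, c in enumerate(sc.column_ids)}
    columns, ids, types, prov, sources = [], [], [], [], []
    for t in sorted(targets.targets):
        target = targets[t]
        if target == 0:
            continue
        cells = sorted(c for c in ann.cells_of_type(t) if c in col_of)
        if not cells:
            raise ValueError(f"cell type {t!r} has no cells in the matrix")
        rng = _type_rng(seed, t)
        n = len(cells)
        if n >= target:
            keep = sorted(rng.choice(n, size=target, replace=False).tolist())
            originals, n_generated = [cells[i] for i in keep], 0
        else:
            originals, n_generated = list(cells), target - n
        for c in originals:
            columns.append(sc.values[:, col_of[c]])
            ids.append(f"{t}|orig|{c}")
            types.append(t)
            prov.append("original")
            sources.append(c)
        if n_generated:
            block = sc.values[:, [col_of[c] for c in cells]]  # genes × n
            donor = rng.integers(0, n, size=(sc.n_genes, n_generated))
            synth = np.take_along_axis(block, donor, axis=1)
            for j in range(n_generated):
                columns.append(synth[:, j])
                ids.append(f"{t}|gen{j}")
                types.append(t)
                prov.append("generated")
                sources.append(None)
    return _pool_from_columns(sc, columns, ids, types, prov, sources, seed)


def sample_pool(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    targets: TypeTargets,
    seed: int,
    mode: str = "duplication",
) -> SampledPool:
    if mode == "duplication":
        return sample_duplication(sc, ann, targets, seed)
    if mode == "generation":
        return sample_generation(sc, ann, targets, seed)
    raise ValueError(f"unknown sampling mode {mode!r}")
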