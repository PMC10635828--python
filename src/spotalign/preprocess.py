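"""Normalization and gene-space harmonization.

The mapping cost is computed on log2(CPM + 1) profiles over the full
set of genes shared by the single-cell and spatial matrices: no
variable-gene selection and no dimension reduction.
"""
from __future__ import annotations

import logging

import numpy as np

from .types import CPM_TOTAL, ExpressionMatrix

logger = logging.getLogger(__name__)


def normalize_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every nonzero column to a total of 1e6 counts.

    All-zero columns are left at zero with a warning.
    """
    if m.layer != "raw":
        raise ValueError(f"normalize_cpm expects layer='raw', got {m.layer!r}")
    sums = m.values.sum(axis=0)
    zero = sums == 0
    if np.any(zero):
        logger.warning(
            "%d all-zero column(s) left unnormalized", int(zero.sum())
        )
    scale = np.where(zero, 1.0, CPM_TOTAL / np.where(zero, 1.0, sums))
    return ExpressionMatrix(
        m.values * scale[None, :], list(m.gene_ids), list(m.column_ids), layer="cpm"
    )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """value -> log2(value + 1), so zeros stay zero."""
    if m.layer != "cpm":
        raise ValueError(f"log2_transform expects layer='cpm', got {m.layer!r}")
    return ExpressionMatrix(
        np.log2(m.values + 1.0),
        list(m.gene_ids),
        list(m.column_ids),
        layer="log2cpm",
    )


def log_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convenience: raw -> CPM -> log2(CPM + 1)."""
    return log2_transform(normalize_cpm(m))


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Restrict both matrices to their shared genes, sorted lexicographically.

    Returns the two row-subset matrices and the ordered shared gene list G.
    """
    if a.layer != b.layer:
        raise ValueError(f"layer mismatch: {a.layer!r} vs {b.layer!r}")
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("gene sets are disjoint; nothing to align on")
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes")
    return a.subset_genes(shared), b.subset_genes(shared), shared
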