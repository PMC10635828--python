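"""Readers and writers for the on-disk formats.

Expression matrices come either as a 10x-style MatrixMarket triplet
directory (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) or as a
plain dense TSV (first column gene ids, header row column ids).  All
tables are tab-separated UTF-8 with '.' as decimal point.  Labels are
stripped of surrounding whitespace on read.
"""
from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import mmread

from .types import (
    CellAnnotation,
    CellTypeFractions,
    ExpressionMatrix,
    MappingRow,
    MappingTable,
    SpotGeometry,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MAPPING_COLUMNS = [
    "query_cell_id",
    "assigned_spot_id",
    "sub_spot_index",
    "cell_type",
    "provenance",
    "confidence",
]


def _read_name_file(path: Path) -> list[str]:
    """First tab-separated field of each line, whitespace-trimmed."""
    names = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            names.append(line.split("\t")[0].strip())
    return names


def _find_triplet_file(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        p = directory / stem
        if p.exists():
            return p
    raise FileNotFoundError(
        f"none of {stems} found in triplet directory {directory}"
    )


def read_expression(path: PathLike, format: str = "auto") -> ExpressionMatrix:
    """Read an expression matrix as raw counts.

    Parameters
    ----------
    path
        A triplet directory (``format="mtx_dir"``) or a dense TSV file
        (``format="tsv"``).  ``"auto"`` dispatches on whether *path* is
        a directory.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx_dir" if path.is_dir() else "tsv"
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "tsv":
        return _read_dense_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx_dir(directory: Path) -> ExpressionMatrix:
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx = _find_triplet_file(directory, ("matrix.mtx", "expression.mtx"))
    genes = _find_triplet_file(directory, ("genes.tsv", "features.tsv"))
    barcodes = _find_triplet_file(directory, ("barcodes.tsv",))
    values = np.asarray(mmread(str(mtx)).todense(), dtype=float)
    gene_ids = _read_name_file(genes)
    column_ids = _read_name_file(barcodes)
    if values.shape[0] != len(gene_ids):
        raise ValueError(
            f"{mtx.name} declares {values.shape[0]} rows but "
            f"{genes.name} lists {len(gene_ids)} genes"
        )
    if values.shape[1] != len(column_ids):
        raise ValueError(
            f"{mtx.name} declares {values.shape[1]} columns but "
            f"{barcodes.name} lists {len(column_ids)} barcodes"
        )
    return ExpressionMatrix(values, gene_ids, column_ids, layer="raw")


def _read_dense_tsv(path: Path) -> ExpressionMatrix:
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = [str(g).strip() for g in df.index]
    dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gene id {dupes[0]!r} in {path}")
    column_ids = [str(c).strip() for c in df.columns]
    return ExpressionMatrix(
        df.to_numpy(dtype=float), gene_ids, column_ids, layer="raw"
    )


def write_expression_tsv(m: ExpressionMatrix, path: PathLike) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_cell_annotations(path: PathLike, header: bool = True) -> CellAnnotation:
    """Two-column (cell_id, cell_type) table; labels are trimmed."""
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None, dtype=str
    ).iloc[:, :2]
    df.columns = ["cell_id", "cell_type"]
    cell_ids = [str(c).strip() for c in df["cell_id"]]
    dupes = pd.Index(cell_ids)[pd.Index(cell_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate cell id {dupes[0]!r} in {path}")
    return CellAnnotation(
        {c: str(t).strip() for c, t in zip(cell_ids, df["cell_type"])}
    )


def write_cell_annotations(ann: CellAnnotation, path: PathLike) -> None:
    pd.DataFrame(
        {"cell_id": list(ann.types), "cell_type": list(ann.types.values())}
    ).to_csv(path, sep="\t", index=False)


def read_coordinates(path: PathLike, header: bool = True) -> SpotGeometry:
    df = pd.read_csv(path, sep="\t", header=0 if header else None).iloc[:, :3]
    df.columns = ["spot_id", "x", "y"]
    spot_ids = [str(s).strip() for s in df["spot_id"]]
    dupes = pd.Index(spot_ids)[pd.Index(spot_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate spot id {dupes[0]!r} in {path}")
    return SpotGeometry(
        {
            s: (float(x), float(y))
            for s, x, y in zip(spot_ids, df["x"], df["y"])
        }
    )


def write_coordinates(geom: SpotGeometry, path: PathLike) -> None:
    pd.DataFrame(
        {
            "spot_id": list(geom.coords),
            "x": [c[0] for c in geom.coords.values()],
            "y": [c[1] for c in geom.coords.values()],
        }
    ).to_csv(path, sep="\t", index=False)


#: |sum - 1| below this counts as exactly 1; up to FRACTION_SUM_MAX the
#: table is rescaled to unit sum with a warning; beyond it, rejected.
FRACTION_SUM_TOL = 1e-9
FRACTION_SUM_MAX = 0.05


def read_fractions(path: PathLike, header: bool = True) -> CellTypeFractions:
    """Two-column (cell_type, fraction) table.

    A sum within ``FRACTION_SUM_TOL`` of 1 is accepted as-is; a deviation
    up to ``FRACTION_SUM_MAX`` is rescaled to unit sum with a warning;
    anything larger is an error.
    """
    df = pd.read_csv(path, sep="\t", header=0 if header else None).iloc[:, :2]
    df.columns = ["cell_type", "fraction"]
    types = [str(t).strip() for t in df["cell_type"]]
    fracs = df["fraction"].to_numpy(dtype=float)
    if np.any(fracs < 0):
        bad = types[int(np.argmax(fracs < 0))]
        raise ValueError(f"negative fraction for cell type {bad!r}")
    total = fracs.sum()
    if abs(total - 1.0) > FRACTION_SUM_MAX:
        raise ValueError(
            f"fractions sum to {total:.6g}; deviation from 1 exceeds "
            f"{FRACTION_SUM_MAX}"
        )
    if abs(total - 1.0) > FRACTION_SUM_TOL:
        logger.warning(
            "fractions in %s sum to %.6g; rescaling to unit sum", path, total
        )
    if total <= 0:
        raise ValueError("fractions sum to zero")
    fracs = fracs / total
    return CellTypeFractions(dict(zip(types, fracs)))


def write_fractions(f: CellTypeFractions, path: PathLike) -> None:
    pd.DataFrame(
        {"cell_type": list(f.fractions), "fraction": list(f.fractions.values())}
    ).to_csv(path, sep="\t", index=False)


def read_cell_counts(path: PathLike, header: bool = True) -> dict[str, int]:
    """Optional per-spot cell counts from segmentation, (spot_id, n_cells)."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None).iloc[:, :2]
    df.columns = ["spot_id", "n_cells"]
    counts = {}
    for s, n in zip(df["spot_id"], df["n_cells"]):
        n = int(n)
        if n < 1:
            raise ValueError(f"cell count < 1 for spot {s!r}")
        counts[str(s).strip()] = n
    return counts


def write_mapping(table: MappingTable, path: PathLike) -> None:
    """Write a mapping as TSV with fixed column order; absent confidence
    is emitted as ``NA``."""
    df = table.to_frame()[MAPPING_COLUMNS].copy()
    df["confidence"] = [
        "NA" if c is None else repr(float(c)) for c in df["confidence"]
    ]
    df.to_csv(path, sep="\t", index=False)


def read_mapping(path: PathLike) -> MappingTable:
    df = pd.read_csv(path, sep="\t", dtype={"query_cell_id": str,
                                            "assigned_spot_id": str,
                                            "cell_type": str,
                                            "provenance": str,
                                            "confidence": str})
    rows = []
    for _, r in df.iterrows():
        conf = r["confidence"]
        conf = None if (pd.isna(conf) or conf == "NA") else float(conf)
        rows.append(
            MappingRow(
                query_cell_id=str(r["query_cell_id"]),
                assigned_spot_id=str(r["assigned_spot_id"]),
                sub_spot_index=int(r["sub_spot_index"]),
                cell_type=str(r["cell_type"]),
                provenance=str(r["provenance"]),
                confidence=conf,
            )
        )
    return MappingTable(rows)
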