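"""Cells-per-spot estimation, per-type integer targets, sub-spot expansion.

A spot captures RNA from several cells; its total UMI count proxies how
many.  The estimator fits a line through two anchor points in log2-UMI
space — the lowest-UMI spot is assumed to hold one cell and the mean-UMI
spot the user-supplied mean — then evaluates the line per spot.  Each
spot with n_s cells is expanded into n_s identical "sub-spots", each of
which will receive exactly one cell in the assignment.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import CellTypeFractions, ExpressionMatrix

#: default mean cells per spot by platform generation
MEAN_CELLS_VISIUM = 5.0
MEAN_CELLS_LEGACY_ST = 20.0


@dataclass
class SpotModel:
    """Per-spot integer cell counts and the sub-spot expansion map."""

    spot_ids: list[str]
    n: dict[str, int]

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        if set(self.spot_ids) != set(self.n):
            raise ValueError("spot_ids and counts disagree")
        for s, c in self.n.items():
            if int(c) < 1:
                raise ValueError(f"cells per spot must be >= 1 (spot {s!r})")
        self.n = {s: int(c) for s, c in self.n.items()}

    @property
    def L(self) -> int:
        return sum(self.n.values())

    def counts_array(self) -> np.ndarray:
        return np.array([self.n[s] for s in self.spot_ids], dtype=int)

    def subspot_to_spot(self) -> list[str]:
        """Sub-spot index (0..L-1) → parent spot id; indices contiguous
        per spot, in spot_ids order."""
        out: list[str] = []
        for s in self.spot_ids:
            out.extend([s] * self.n[s])
        return out


@dataclass
class TypeTargets:
    """Integer number of cells to map per cell type; sums to L."""

    targets: dict[str, int]

    def __post_init__(self) -> None:
        for t, c in self.targets.items():
            if int(c) < 0:
                raise ValueError(f"negative target for {t!r}")
        self.targets = {str(t): int(c) for t, c in self.targets.items()}

    @property
    def total(self) -> int:
        return sum(self.targets.values())

    def __getitem__(self, t: str) -> int:
        return self.targets[t]


def log2_umi(st_raw: ExpressionMatrix) -> np.ndarray:
    """Per-spot predictor u_s = log2(total UMI + 1)."""
    return np.log2(st_raw.values.sum(axis=0) + 1.0)


def estimate_cells_per_spot(
    st_raw: ExpressionMatrix, mean_cells: float
) -> SpotModel:
    """Two-point log-linear estimate of cells per spot.

    The line passes through (min_s u_s, 1) and (mean_s u_s, mean_cells),
    with u_s = log2(UMI sum + 1); estimates are rounded to the nearest
    integer and clamped at a minimum of one cell.
    """
    if st_raw.layer != "raw":
        raise ValueError("estimate_cells_per_spot expects raw counts")
    if st_raw.n_columns < 2:
        raise ValueError("need at least 2 spots")
    if mean_cells < 1:
        raise ValueError("mean_cells must be >= 1")
    u = log2_umi(st_raw)
    u_min, u_mean = float(u.min()), float(u.mean())
    if np.isclose(u_min, u_mean):
        # all spots carry equal RNA content: no slope to fit
        est = np.full(len(u), round(mean_cells))
    else:
        slope = (mean_cells - 1.0) / (u_mean - u_min)
        est = np.rint(1.0 + slope * (u - u_min))
    est = np.maximum(est.astype(int), 1)
    return SpotModel(list(st_raw.column_ids), dict(zip(st_raw.column_ids, est)))


def spot_model_from_counts(counts: Mapping[str, int]) -> SpotModel:
    """Accept externally supplied (e.g. segmentation-based) counts."""
    spot_ids = list(counts)
    return SpotModel(spot_ids, dict(counts))


def type_targets_from_fractions(f: CellTypeFractions, L: int) -> TypeTargets:
    """Largest-remainder apportionment of L cells across types.

    Ties on the remainder are broken by descending fraction, then by
    lexicographic type name.  Types with zero fraction get zero cells
    and are never mapped.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    types = f.types()
    fracs = np.array([f[t] for t in types], dtype=float)
    quota = fracs * L
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = L - int(base.sum())
    # order: remainder desc, fraction desc, name asc
    order = sorted(
        range(len(types)), key=lambda i: (-remainder[i], -fracs[i], types[i])
    )
    for i in order[:short]:
        base[i] += 1
    targets = dict(zip(types, (int(b) for b in base)))
    assert sum(targets.values()) == L
    return TypeTargets(targets)


def expand_subspots(st_norm: ExpressionMatrix, sm: SpotModel) -> ExpressionMatrix:
    """Replicate spot s's column n_s times, yielding the L-column matrix
    the assignment is solved against.  Column ids are 'spot::r<i>'."""
    if st_norm.layer != "log2cpm":
        raise ValueError("expand_subspots expects layer='log2cpm'")
    if set(st_norm.column_ids) != set(sm.spot_ids):
        raise ValueError("spot ids of matrix and SpotModel disagree")
    col_of = {s: i for i, s in enumerate(st_norm.column_ids)}
    take: list[int] = []
    ids: list[str] = []
    for s in sm.spot_ids:
        for r in range(sm.n[s]):
            take.append(col_of[s])
            ids.append(f"{s}::r{r}")
    return ExpressionMatrix(
        st_norm.values[:, take], list(st_norm.gene_ids), ids, layer="log2cpm"
    )
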