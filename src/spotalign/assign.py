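"""Cost-matrix construction and cell-to-sub-spot assignment.

Cells and sub-spots are matched by solving a balanced linear assignment
problem: with K pool cells and L sub-spots (K = L), the cost of placing
cell k at sub-spot l is the negated correlation (or the Euclidean
distance) between their log2-CPM profiles over the shared genes, and
the optimal bijection minimizes the total cost.  Two solvers are
offered: the exact shortest-augmenting-path solver with dual
optimality certificates, and an integer-rounded variant that solves
``round(d * scale)`` exactly (mirroring integer-programming
approximations whose costs must be integral).  A per-cell argmax over
spots, with no capacity constraint, is included purely as a baseline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from . import preprocess
from .lap import solve_lap, solve_lap_bruteforce
from .sampling import SampledPool, sample_pool
from .spot_model import (
    SpotModel,
    estimate_cells_per_spot,
    expand_subspots,
    spot_model_from_counts,
    type_targets_from_fractions,
)
from .types import (
    CellAnnotation,
    CellTypeFractions,
    ExpressionMatrix,
    MappingRow,
    MappingTable,
)

METRICS = ("neg_pearson", "neg_spearman", "euclidean")

_METRIC_ALIASES = {
    "pearson": "neg_pearson",
    "spearman": "neg_spearman",
    "euclidean": "euclidean",
    "neg_pearson": "neg_pearson",
    "neg_spearman": "neg_spearman",
}

#: relative tolerance for dual-feasibility checks
DUAL_EPS_REL = 1e-8


def canonical_metric(metric: str) -> str:
    try:
        return _METRIC_ALIASES[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass
class CostMatrix:
    """Balanced K × L cost matrix d_kl between pool cells and sub-spots."""

    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.metric = canonical_metric(self.metric)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError(
                f"cost matrix must be balanced (square); got {self.d.shape}"
            )
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite cost entries")
        if self.metric in ("neg_pearson", "neg_spearman"):
            if self.d.min() < -1 - 1e-9 or self.d.max() > 1 + 1e-9:
                raise ValueError("correlation costs must lie in [-1, 1]")
        elif np.any(self.d < 0):
            raise ValueError("euclidean costs must be nonnegative")

    @property
    def K(self) -> int:
        return self.d.shape[0]


@dataclass
class Assignment:
    """An optimal bijection row k → column l with optimality evidence."""

    perm: np.ndarray
    total_cost: float
    solver: str  # jv_exact | integer_approx | brute_force
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.perm = np.asarray(self.perm, dtype=int)
        k = len(self.perm)
        if sorted(self.perm.tolist()) != list(range(k)):
            raise ValueError("perm is not a permutation")

    def reduced_costs(self, d: np.ndarray) -> np.ndarray:
        if self.u is None or self.v is None:
            raise ValueError(f"no duals available for solver {self.solver!r}")
        return d - self.u[:, None] - self.v[None, :]


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Column z-scores over genes; zero-variance columns become all-zero,
    making their correlation with anything 0 (neutral cost)."""
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def pairwise_cost(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """Cost between columns of a (genes × K) and b (genes × L)."""
    metric = canonical_metric(metric)
    g = a.shape[0]
    if g != b.shape[0]:
        raise ValueError("gene dimension mismatch")
    if g < 2:
        raise ValueError("need at least 2 shared genes")
    if metric == "euclidean":
        return cdist(a.T, b.T, metric="euclidean")
    if metric == "neg_spearman":
        a = rankdata(a, axis=0, method="average")
        b = rankdata(b, axis=0, method="average")
    za = _standardize_columns(a)
    zb = _standardize_columns(b)
    corr = (za.T @ zb) / g
    return np.clip(-corr, -1.0, 1.0)


def build_cost_matrix(
    pool: SampledPool, subspots: ExpressionMatrix, metric: str = "neg_pearson"
) -> CostMatrix:
    if pool.expr.gene_ids != subspots.gene_ids:
        raise ValueError("pool and sub-spots must share identical gene ordering")
    if pool.K != subspots.n_columns:
        raise ValueError(
            f"unbalanced problem: {pool.K} cells vs {subspots.n_columns} sub-spots"
        )
    d = pairwise_cost(pool.expr.values, subspots.values, metric)
    return CostMatrix(d, metric)


def solve_exact(c: CostMatrix | np.ndarray) -> Assignment:
    """Shortest-augmenting-path solve with dual certificates."""
    d = c.d if isinstance(c, CostMatrix) else np.asarray(c, dtype=float)
    perm, u, v = solve_lap(d)
    total = float(d[np.arange(len(perm)), perm].sum())
    a = Assignment(perm, total, "jv_exact", u=u, v=v)
    _certify(a, d)
    return a


def _certify(a: Assignment, d: np.ndarray) -> None:
    eps = DUAL_EPS_REL * max(np.abs(d).max(), 1e-300)
    r = a.reduced_costs(d)
    if r.min() < -eps:
        raise AssertionError(
            f"dual infeasibility: min reduced cost {r.min():.3e} < -{eps:.3e}"
        )
    slack = np.abs(r[np.arange(len(a.perm)), a.perm]).max() if len(a.perm) else 0.0
    if slack > eps:
        raise AssertionError(
            f"complementary slackness violated: |r| on matched edge {slack:.3e}"
        )


def solve_integer_approx(c: CostMatrix | np.ndarray, scale: int = 10**6) -> Assignment:
    """Exact solve of the integer-rounded costs round(d * scale).

    Total cost is reported on the original real costs.  Rounding loses
    precision below 1/scale, so the permutation can differ from
    :func:`solve_exact` on near-ties.
    """
    d = c.d if isinstance(c, CostMatrix) else np.asarray(c, dtype=float)
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    scaled = np.rint(d * scale)
    if np.abs(scaled).max() >= 2**53:
        raise OverflowError("scaled costs exceed exact integer range")
    rows, cols = linear_sum_assignment(scaled)
    perm = np.empty(d.shape[0], dtype=int)
    perm[rows] = cols
    total = float(d[np.arange(len(perm)), perm].sum())
    return Assignment(perm, total, "integer_approx")


def solve_bruteforce(c: CostMatrix | np.ndarray) -> Assignment:
    d = c.d if isinstance(c, CostMatrix) else np.asarray(c, dtype=float)
    perm, total = solve_lap_bruteforce(d)
    return Assignment(perm, total, "brute_force")


_SOLVERS = {
    "exact": solve_exact,
    "jv_exact": solve_exact,
    "integer": solve_integer_approx,
    "integer_approx": solve_integer_approx,
}


def _mapping_from_assignment(
    pool: SampledPool, sm: SpotModel, assignment: Assignment
) -> MappingTable:
    subspot_spot = sm.subspot_to_spot()
    rows = []
    for k in range(pool.K):
        l = int(assignment.perm[k])
        src = pool.source_cell_ids[k]
        rows.append(
            MappingRow(
                query_cell_id=src if src is not None else pool.expr.column_ids[k],
                assigned_spot_id=subspot_spot[l],
                sub_spot_index=l,
                cell_type=pool.cell_types[k],
                provenance=pool.provenance[k],
            )
        )
    return MappingTable(rows)


def map_cells(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    st: ExpressionMatrix,
    fractions: CellTypeFractions,
    mean_cells: Optional[float] = None,
    cell_counts: Optional[Mapping[str, int]] = None,
    metric: str = "neg_pearson",
    mode: str = "duplication",
    solver: str = "exact",
    seed: int = 0,
) -> MappingTable:
    """End-to-end pipeline: normalize, estimate cells per spot, derive
    per-type targets, resample the query cells, expand sub-spots, build
    the cost matrix and solve the balanced assignment.

    Exactly one of ``mean_cells`` (two-point estimator) or
    ``cell_counts`` (externally supplied, e.g. from segmentation) must
    be given.
    """
    if (mean_cells is None) == (cell_counts is None):
        raise ValueError("supply exactly one of mean_cells or cell_counts")
    if sc.layer != "raw" or st.layer != "raw":
        raise ValueError("map_cells expects raw count matrices")

    if cell_counts is not None:
        sm = spot_model_from_counts(cell_counts)
        missing = set(sm.spot_ids) ^ set(st.column_ids)
        if missing:
            raise ValueError(f"cell_counts spots disagree with ST matrix: {sorted(missing)[:5]}")
    else:
        sm = estimate_cells_per_spot(st, float(mean_cells))

    sc_norm = preprocess.log_normalize(sc)
    st_norm = preprocess.log_normalize(st)
    sc_g, st_g, _ = preprocess.intersect_genes(sc_norm, st_norm)

    targets = type_targets_from_fractions(fractions, sm.L)
    pool = sample_pool(sc_g, ann, targets, seed, mode=mode)
    subspots = expand_subspots(st_g, sm)
    cost = build_cost_matrix(pool, subspots, metric)
    try:
        solve = _SOLVERS[solver]
    except KeyError:
        raise ValueError(f"unknown solver {solver!r}")
    assignment = solve(cost)
    return _mapping_from_assignment(pool, sm, assignment)


def baseline_argmax(
    pool: SampledPool,
    spots: ExpressionMatrix,
    metric: str = "neg_pearson",
) -> MappingTable:
    """Naive benchmark: each cell independently takes its best spot.

    No capacity constraint — many cells may pile onto one spot.  The
    sub_spot_index is a synthetic running index (the baseline has no
    sub-spot structure).
    """
    d = pairwise_cost(pool.expr.values, spots.values, metric)
    best = np.argmin(d, axis=1)
    rows = []
    for k in range(pool.K):
        src = pool.source_cell_ids[k]
        rows.append(
            MappingRow(
                query_cell_id=src if src is not None else pool.expr.column_ids[k],
                assigned_spot_id=spots.column_ids[int(best[k])],
                sub_spot_index=k,
                cell_type=pool.cell_types[k],
                provenance=pool.provenance[k],
            )
        )
    return MappingTable(rows)


def map_cells_binned(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    st_single_cell: ExpressionMatrix,
    fractions: CellTypeFractions,
    bin_size: int = 10_000,
    metric: str = "neg_pearson",
    solver: str = "exact",
    seed: int = 0,
) -> MappingTable:
    """Map against a single-cell ST target (one cell per spot) in
    random disjoint bins of up to ``bin_size`` ST cells.

    The query pool is freshly resampled (duplication scheme) for every
    bin; results are concatenated into one table.  With a single bin
    this reduces exactly to :func:`map_cells` with unit spot counts.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    s = st_single_cell.n_columns
    n_bins = int(np.ceil(s / bin_size))
    if n_bins == 1:
        return map_cells(
            sc,
            ann,
            st_single_cell,
            fractions,
            cell_counts={c: 1 for c in st_single_cell.column_ids},
            metric=metric,
            mode="duplication",
            solver=solver,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(s)
    all_rows: list[MappingRow] = []
    offset = 0
    for b in range(n_bins):
        take = order[b * bin_size : (b + 1) * bin_size]
        st_bin = st_single_cell.subset_columns(
            [st_single_cell.column_ids[i] for i in take]
        )
        bin_seed = int((seed + 1_000_003 * (b + 1)) % 2**31)
        sub = map_cells(
            sc,
            ann,
            st_bin,
            fractions,
            cell_counts={c: 1 for c in st_bin.column_ids},
            metric=metric,
            mode="duplication",
            solver=solver,
            seed=bin_seed,
        )
        for r in sub.rows:
            all_rows.append(
                MappingRow(
                    query_cell_id=r.query_cell_id,
                    assigned_spot_id=r.assigned_spot_id,
                    sub_spot_index=offset + r.sub_spot_index,
                    cell_type=r.cell_type,
                    provenance=r.provenance,
                    confidence=r.confidence,
                )
            )
        offset += st_bin.n_columns
    return MappingTable(all_rows)
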