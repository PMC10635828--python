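"""Ground-truth tissue simulation and input-perturbation models.

A synthetic single-cell atlas (negative-binomial counts, log-normal
library sizes, per-type marker blocks) is laid out in the unit square
with configurable spatial structure, then pooled into pseudo-spots on
an m × n grid so that the mean number of cells per nonempty spot hits a
target resolution.  The query dataset is a copy of the atlas optionally
degraded by within-type gene permutation and multiplicative
2^N(0,1) expression noise, emulating cross-platform technical
variation.  Perturbation models for cell-type fractions and cells-per-
spot estimates reproduce the four-fold multiplicative noise scheme used
for robustness analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .spot_model import SpotModel
from .types import (
    CellAnnotation,
    CellTypeFractions,
    ExpressionMatrix,
    SpotGeometry,
)

logger = logging.getLogger(__name__)

#: spot resolutions (mean cells per spot) used in benchmarking
SPOT_RESOLUTIONS = (5, 15, 30)
#: expression-noise levels (fraction of genes perturbed per cell)
NOISE_LEVELS = (0.05, 0.10, 0.25)
#: count-perturbation tuning for a five-cells-per-spot design
COUNT_PERTURBATION_P_5 = 1.4

LAYOUTS = ("blocks", "gradient", "random")


@dataclass
class SimulatedTissue:
    """A tissue with known single-cell composition."""

    atlas: ExpressionMatrix          # raw counts, unique single cells
    annotation: CellAnnotation
    positions: dict[str, tuple[float, float]]   # cell_id -> (x, y)
    grid: tuple[int, int]            # (m rows, n cols) over the unit square
    spot_counts: ExpressionMatrix    # raw pseudo-bulk, nonempty spots only
    spot_geometry: SpotGeometry      # spot centers
    truth: dict[str, str]            # cell_id -> spot_id
    query: ExpressionMatrix          # noised copy of the atlas
    noise_p: float
    seed: int

    def true_cell_counts(self) -> dict[str, int]:
        out: dict[str, int] = {s: 0 for s in self.spot_counts.column_ids}
        for s in self.truth.values():
            out[s] += 1
        return out

    def true_fractions(self) -> CellTypeFractions:
        census = self.annotation.census()
        total = sum(census.values())
        return CellTypeFractions({t: c / total for t, c in census.items()})


def generate_atlas(
    n_types: int,
    n_genes: int = 800,
    cells_per_type: int = 50,
    marker_frac: float = 0.1,
    effect_size: float = 5.0,
    dispersion: float = 0.15,
    mean_library_size: float = 2000.0,
    library_sigma: float = 0.35,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Synthesize a raw-count single-cell atlas with distinct cell types.

    Each type up-regulates a disjoint block of ``marker_frac · n_genes``
    marker genes by ``effect_size``; counts follow a gamma–Poisson
    (negative-binomial) model with log-normal per-cell library sizes.
    ``effect_size = 1`` yields types indistinguishable in expectation.
    """
    if min(n_types, n_genes, cells_per_type) < 1:
        raise ValueError("all atlas dimensions must be positive")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    n_markers = int(round(marker_frac * n_genes))
    marker_sets: list[np.ndarray] = []
    if n_markers * n_types <= n_genes:
        gene_order = rng.permutation(n_genes)
        for t in range(n_types):
            marker_sets.append(gene_order[t * n_markers : (t + 1) * n_markers])
    else:  # not enough genes for disjoint blocks: draw independently
        for t in range(n_types):
            marker_sets.append(rng.choice(n_genes, size=n_markers, replace=False))

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    columns = []
    cell_ids = []
    types: dict[str, str] = {}
    shape = 1.0 / dispersion
    for t in range(n_types):
        tname = f"type{t}"
        mean_t = base.copy()
        mean_t[marker_sets[t]] *= effect_size
        p_gene = mean_t / mean_t.sum()
        libs = rng.lognormal(
            mean=np.log(mean_library_size), sigma=library_sigma, size=cells_per_type
        )
        mu = p_gene[:, None] * libs[None, :]
        lam = rng.gamma(shape=shape, scale=mu / shape)
        counts = rng.poisson(lam).astype(float)
        for c in range(cells_per_type):
            cid = f"{tname}_c{c:04d}"
            cell_ids.append(cid)
            types[cid] = tname
        columns.append(counts)
    values = np.concatenate(columns, axis=1)
    return ExpressionMatrix(values, gene_ids, cell_ids, layer="raw"), CellAnnotation(types)


def _positions_for_layout(
    ann: CellAnnotation, cell_ids: list[str], layout: str, rng: np.random.Generator
) -> dict[str, tuple[float, float]]:
    types = ann.cell_types()
    t_index = {t: i for i, t in enumerate(types)}
    T = len(types)
    pos = {}
    for cid in cell_ids:
        i = t_index[ann[cid]]
        if layout == "blocks":
            # contiguous vertical strip per type
            x = (i + rng.uniform()) / T
            y = rng.uniform()
        elif layout == "gradient":
            center = (i + 0.5) / T
            x = float(np.clip(rng.normal(center, 0.5 / T), 0.0, 1.0 - 1e-9))
            y = rng.uniform()
        elif layout == "random":
            x = rng.uniform()
            y = rng.uniform()
        else:
            raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
        pos[cid] = (float(min(x, 1.0 - 1e-9)), float(min(y, 1.0 - 1e-9)))
    return pos


def lay_out_and_pool(
    atlas: ExpressionMatrix,
    ann: CellAnnotation,
    layout: str = "blocks",
    target_mean_cells_per_spot: float = 5,
    seed: int = 0,
) -> SimulatedTissue:
    """Place atlas cells in the unit square and pool them on a grid.

    The grid dimension m × n is chosen so the expected cells per spot
    matches the target; pseudo-bulk spot profiles are exact raw-count
    sums over member cells, so totals are conserved.
    """
    total = atlas.n_columns
    if target_mean_cells_per_spot > total:
        raise ValueError("target mean cells per spot exceeds total cells")
    if set(atlas.column_ids) != set(ann.types):
        raise ValueError("atlas columns and annotation disagree")
    rng = np.random.default_rng(seed)
    pos = _positions_for_layout(ann, list(atlas.column_ids), layout, rng)

    n_spots_target = max(1, int(round(total / target_mean_cells_per_spot)))
    m = max(1, int(round(np.sqrt(n_spots_target))))
    n = max(1, int(round(n_spots_target / m)))

    # bin cells into grid cells
    members: dict[tuple[int, int], list[str]] = {}
    for cid, (x, y) in pos.items():
        ij = (min(int(y * m), m - 1), min(int(x * n), n - 1))
        members.setdefault(ij, []).append(cid)

    col_of = {c: k for k, c in enumerate(atlas.column_ids)}
    spot_ids, spot_cols, coords = [], [], {}
    truth: dict[str, str] = {}
    for (i, j) in sorted(members):
        sid = f"spot_{i}_{j}"
        cells = members[(i, j)]
        spot_ids.append(sid)
        spot_cols.append(atlas.values[:, [col_of[c] for c in cells]].sum(axis=1))
        coords[sid] = ((j + 0.5) / n, (i + 0.5) / m)
        for c in cells:
            truth[c] = sid
    spot_counts = ExpressionMatrix(
        np.stack(spot_cols, axis=1), list(atlas.gene_ids), spot_ids, layer="raw"
    )
    return SimulatedTissue(
        atlas=atlas,
        annotation=ann,
        positions=pos,
        grid=(m, n),
        spot_counts=spot_counts,
        spot_geometry=SpotGeometry(coords),
        truth=truth,
        query=atlas,
        noise_p=0.0,
        seed=seed,
    )


def permute_within_type(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    fraction: float = 0.2,
    seed: int = 0,
) -> ExpressionMatrix:
    """De-duplicate cells by swapping part of each transcriptome.

    For every cell, a random ``fraction`` of genes takes its values
    from one randomly chosen cell of the same type that is neither the
    cell itself nor a value-identical duplicate of it.  Types with a
    single cell are left unchanged with a warning.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = expr.values.copy()
    n_swap = int(round(fraction * expr.n_genes))
    if n_swap == 0:
        return ExpressionMatrix(out, list(expr.gene_ids), list(expr.column_ids), expr.layer)
    col_of = {c: i for i, c in enumerate(expr.column_ids)}
    for t in ann.cell_types():
        cells = [c for c in ann.cells_of_type(t) if c in col_of]
        if len(cells) < 2:
            logger.warning("cell type %r has a single cell; left unchanged", t)
            continue
        idx = [col_of[c] for c in cells]
        for ci in idx:
            donors = [j for j in idx if j != ci
                      and not np.array_equal(expr.values[:, j], expr.values[:, ci])]
            if not donors:
                logger.warning(
                    "cell %r has no distinct same-type donor; left unchanged",
                    expr.column_ids[ci],
                )
                continue
            donor = donors[rng.integers(0, len(donors))]
            genes = rng.choice(expr.n_genes, size=n_swap, replace=False)
            out[genes, ci] = expr.values[genes, donor]
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.column_ids), expr.layer)


def add_expression_noise(
    expr: ExpressionMatrix, p: float, seed: int = 0
) -> ExpressionMatrix:
    """Multiply a random fraction p of each cell's genes by 2^N(0,1).

    The multiplier's median is 1 (2^0), so perturbed entries are scaled
    up and down symmetrically in log space.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if expr.layer != "raw":
        raise ValueError("noise is applied to raw counts")
    rng = np.random.default_rng(seed)
    out = expr.values.copy()
    n_perturb = int(round(p * expr.n_genes))
    for c in range(expr.n_columns):
        if n_perturb == 0:
            break
        genes = rng.choice(expr.n_genes, size=n_perturb, replace=False)
        out[genes, c] *= 2.0 ** rng.normal(0.0, 1.0, size=n_perturb)
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.column_ids), expr.layer)


def simulate_tissue(
    n_types: int = 5,
    n_genes: int = 800,
    cells_per_type: int = 50,
    layout: str = "blocks",
    target_mean_cells_per_spot: float = 5,
    noise_p: float = 0.0,
    permute_fraction: float = 0.0,
    seed: int = 0,
    **atlas_kwargs,
) -> SimulatedTissue:
    """Convenience composition: atlas → layout/pooling → noised query."""
    atlas, ann = generate_atlas(
        n_types, n_genes, cells_per_type, seed=seed, **atlas_kwargs
    )
    tissue = lay_out_and_pool(
        atlas, ann, layout=layout,
        target_mean_cells_per_spot=target_mean_cells_per_spot, seed=seed + 1,
    )
    query = atlas
    if permute_fraction > 0:
        query = permute_within_type(query, ann, permute_fraction, seed=seed + 2)
    if noise_p > 0:
        query = add_expression_noise(query, noise_p, seed=seed + 3)
    tissue.query = query
    tissue.noise_p = noise_p
    return tissue


def fraction_perturbation_multipliers(
    f: CellTypeFractions, seed: int = 0
) -> dict[str, float]:
    """The pre-normalization multipliers 2^z applied per type.

    z = max(-2, min(2, y)) with y ~ N(0, sigma^2) and
    sigma = 1 / (2 x^(1/3)): rarer types get proportionally larger
    error, and the clamp confines every multiplier to [1/4, 4].
    Zero-fraction types get multiplier 1 (they pass through as zero).
    """
    rng = np.random.default_rng(seed)
    mult: dict[str, float] = {}
    for t in f.types():
        x = f[t]
        if x == 0:
            mult[t] = 1.0
            continue
        sigma = 1.0 / (2.0 * x ** (1.0 / 3.0))
        z = float(np.clip(rng.normal(0.0, sigma), -2.0, 2.0))
        mult[t] = 2.0**z
    return mult


def perturb_fractions(f: CellTypeFractions, seed: int = 0) -> CellTypeFractions:
    """Four-fold multiplicative noise on fractional abundances.

    Each fraction is scaled by its 2^z multiplier (see
    :func:`fraction_perturbation_multipliers`) and the result is
    renormalized to unit sum.  Zero fractions pass through unchanged.
    """
    mult = fraction_perturbation_multipliers(f, seed)
    perturbed = {t: f[t] * mult[t] for t in f.types()}
    total = sum(perturbed.values())
    return CellTypeFractions({t: v / total for t, v in perturbed.items()})


def perturb_cell_counts(sm: SpotModel, p: float, seed: int = 0) -> SpotModel:
    """Multiplicative noise on per-spot cell counts.

    Per spot with count n: sigma = p / n^(1/3), y ~ N(0, sigma^2), and
    the perturbed count is max(1, min(n · Round(2^y), ceil(1.1 M)))
    with M the original maximum.  p tunes how far the perturbed counts
    decorrelate from the originals (p = 1.4 for a five-cells-per-spot
    design).
    """
    if p <= 0:
        raise ValueError("tuning p must be positive")
    rng = np.random.default_rng(seed)
    counts = sm.counts_array()
    cap = int(np.ceil(1.1 * counts.max()))
    new = {}
    for s in sm.spot_ids:
        n = sm.n[s]
        sigma = p / n ** (1.0 / 3.0)
        y = rng.normal(0.0, sigma)
        factor = int(np.rint(2.0**y))
        new[s] = int(max(1, min(n * factor, cap)))
    return SpotModel(list(sm.spot_ids), new)


def truth_mapping(tissue: SimulatedTissue) -> "MappingTable":
    """The ground-truth assignment of a simulated tissue as a
    MappingTable (every cell at its true spot, provenance=original)."""
    from .types import MappingRow, MappingTable

    rows = [
        MappingRow(
            query_cell_id=c,
            assigned_spot_id=tissue.truth[c],
            sub_spot_index=k,
            cell_type=tissue.annotation[c],
            provenance="original",
        )
        for k, c in enumerate(tissue.atlas.column_ids)
    ]
    return MappingTable(rows)


def plant_swapped_errors(
    mapping: "MappingTable",
    geometry: SpotGeometry,
    ann: CellAnnotation,
    fraction: float = 0.10,
    min_distance: float = 0.4,
    seed: int = 0,
) -> tuple["MappingTable", set[str]]:
    """Deliberately corrupt a mapping by swapping spot assignments
    between pairs of cells of different types whose spots are at least
    ``min_distance`` apart.

    Returns the corrupted table and the set of swapped cell ids; used
    to probe whether confidence scores can flag misplaced cells.
    """
    from .types import MappingRow, MappingTable

    rng = np.random.default_rng(seed)
    rows = list(mapping.rows)
    n_plant = int(fraction * len(rows)) // 2 * 2
    order = list(rng.permutation(len(rows)))
    assigned = {i: rows[i].assigned_spot_id for i in range(len(rows))}
    used: set[int] = set()
    planted: set[str] = set()
    pos = 0
    while len(planted) < n_plant and pos < len(order):
        a = order[pos]
        pos += 1
        if a in used:
            continue
        for b in order[pos:]:
            if b in used or rows[a].cell_type == rows[b].cell_type:
                continue
            xa, ya = geometry.coords[assigned[a]]
            xb, yb = geometry.coords[assigned[b]]
            if np.hypot(xa - xb, ya - yb) >= min_distance:
                assigned[a], assigned[b] = assigned[b], assigned[a]
                used.update((a, b))
                planted.update((rows[a].query_cell_id, rows[b].query_cell_id))
                break
    new_rows = [
        MappingRow(
            query_cell_id=r.query_cell_id,
            assigned_spot_id=assigned[i],
            sub_spot_index=r.sub_spot_index,
            cell_type=r.cell_type,
            provenance=r.provenance,
            confidence=r.confidence,
        )
        for i, r in enumerate(rows)
    ]
    return MappingTable(new_rows), planted


def match_to_reference(
    target: ExpressionMatrix,
    target_ann: CellAnnotation,
    reference: ExpressionMatrix,
    reference_ann: CellAnnotation,
) -> dict[str, str]:
    """Match each target column to the most-correlated same-type
    reference column (Pearson); the bead-replacement construction used
    to build high-coverage ground-truth tissues."""
    from .assign import pairwise_cost

    if target.gene_ids != reference.gene_ids:
        raise ValueError("matrices must share identical gene ordering")
    ref_col = {c: i for i, c in enumerate(reference.column_ids)}
    out: dict[str, str] = {}
    for t in sorted(set(target_ann.types.values())):
        t_cells = [c for c in target_ann.cells_of_type(t) if c in set(target.column_ids)]
        r_cells = [c for c in reference_ann.cells_of_type(t) if c in ref_col]
        if not t_cells:
            continue
        if not r_cells:
            raise ValueError(f"no reference cells of type {t!r}")
        tgt = target.subset_columns(t_cells)
        ref = reference.subset_columns(r_cells)
        d = pairwise_cost(tgt.values, ref.values, "neg_pearson")
        best = np.argmin(d, axis=1)
        for c, b in zip(t_cells, best):
            out[c] = r_cells[int(b)]
    return out


def write_tissue(tissue: SimulatedTissue, out_dir) -> dict[str, Path]:
    """Write a SimulatedTissue as the standard TSV files so the CLI
    pipeline consumes it like real data."""
    from . import io as io_mod
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "atlas": out / "atlas_counts.tsv",
        "query": out / "query_counts.tsv",
        "annotations": out / "cell_annotations.tsv",
        "spots": out / "spot_counts.tsv",
        "coordinates": out / "spot_coordinates.tsv",
        "truth": out / "truth.tsv",
        "fractions": out / "true_fractions.tsv",
    }
    io_mod.write_expression_tsv(tissue.atlas, paths["atlas"])
    io_mod.write_expression_tsv(tissue.query, paths["query"])
    io_mod.write_cell_annotations(tissue.annotation, paths["annotations"])
    io_mod.write_expression_tsv(tissue.spot_counts, paths["spots"])
    io_mod.write_coordinates(tissue.spot_geometry, paths["coordinates"])
    pd.DataFrame(
        {"cell_id": list(tissue.truth), "spot_id": list(tissue.truth.values())}
    ).to_csv(paths["truth"], sep="\t", index=False)
    io_mod.write_fractions(tissue.true_fractions(), paths["fractions"])
    return paths
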