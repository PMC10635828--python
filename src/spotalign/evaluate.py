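"""Scoring, quality control and downstream spatial summaries.

Precision (Pr_sc) scores a mapping against ground truth over unique
mapped cells with known locations; generated (synthetic) cells are
excluded.  Confidence scores judge, post hoc, whether a cell type
plausibly belongs to the spot it was mapped to: a linear max-margin
classifier is trained per type on pseudo-bulk profiles of spots with
and without the type, using that type's marker genes, and every mapped
cell inherits the probability of its spot.  Spatial summaries include
the near/far partition by distance to tumor cells, fold-change gene
ranking between the partitions (consumable by pre-ranked GSEA tools),
and a retention index measuring preservation of cell–cell correlation
structure after mapping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spot_model import SpotModel
from .types import (
    CellAnnotation,
    CellTypeFractions,
    ExpressionMatrix,
    MappingTable,
    SpotGeometry,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# precision

@dataclass
class PrecisionReport:
    overall: float
    per_type: dict[str, float]
    tp: int
    denominator: int


def precision(
    mapping: MappingTable, truth: Mapping[str, str]
) -> PrecisionReport:
    """Single-cell mapping precision.

    A cell id that was duplicated counts once; it is correct if any of
    its copies landed on its true spot.  Generated cells have no ground
    truth and are excluded from numerator and denominator.
    """
    spots_by_cell: dict[str, set[str]] = {}
    type_of: dict[str, str] = {}
    for r in mapping.rows:
        if r.provenance == "generated":
            continue
        if r.query_cell_id not in truth:
            raise ValueError(
                f"ground truth missing for mapped cell {r.query_cell_id!r}"
            )
        spots_by_cell.setdefault(r.query_cell_id, set()).add(r.assigned_spot_id)
        type_of[r.query_cell_id] = r.cell_type
    if not spots_by_cell:
        raise ValueError("no mapped cells with ground-truth locations")
    tp_by_type: dict[str, int] = {}
    n_by_type: dict[str, int] = {}
    for cid, spots in spots_by_cell.items():
        t = type_of[cid]
        n_by_type[t] = n_by_type.get(t, 0) + 1
        if truth[cid] in spots:
            tp_by_type[t] = tp_by_type.get(t, 0) + 1
    tp = sum(tp_by_type.values())
    denom = sum(n_by_type.values())
    return PrecisionReport(
        overall=tp / denom,
        per_type={t: tp_by_type.get(t, 0) / n for t, n in sorted(n_by_type.items())},
        tp=tp,
        denominator=denom,
    )


# --------------------------------------------------------------------------
# concordances

class Concordance(NamedTuple):
    r: float
    degenerate: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> Concordance:
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant vector in correlation; reporting r = 0")
        return Concordance(0.0, True)
    return Concordance(float(np.corrcoef(x, y)[0, 1]), False)


def fraction_concordance(
    est: CellTypeFractions, true: CellTypeFractions
) -> Concordance:
    """Pearson r between estimated and true fractions over shared types."""
    shared = sorted(set(est.fractions) & set(true.fractions))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared cell types")
    return _pearson(
        np.array([est[t] for t in shared]), np.array([true[t] for t in shared])
    )


def cells_per_spot_concordance(
    est: SpotModel, true_counts: Mapping[str, int]
) -> Concordance:
    """Pearson r between estimated and true cells per spot."""
    shared = [s for s in est.spot_ids if s in true_counts]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared spots")
    return _pearson(
        np.array([est.n[s] for s in shared], dtype=float),
        np.array([true_counts[s] for s in shared], dtype=float),
    )


# --------------------------------------------------------------------------
# markers

MIN_MARKERS = 5
MAX_MARKERS = 50
#: a gene must be detected in at least this fraction of the type's cells
MIN_DETECTION_FRACTION = 0.10


def find_markers(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    min_markers: int = MIN_MARKERS,
    max_markers: int = MAX_MARKERS,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest rank-sum marker genes per cell type.

    Genes detected in >= 10% of the type's cells are tested with a
    two-sided Wilcoxon rank-sum test against all other cells;
    Benjamini–Hochberg-adjusted p values are ranked ascending among
    genes with positive log2 fold change.  Types yielding fewer than
    ``min_markers`` qualifying genes are skipped with a warning; lists
    are truncated at ``max_markers``.
    """
    types = ann.cell_types()
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    col_of = {c: i for i, c in enumerate(sc.column_ids)}
    out: dict[str, pd.DataFrame] = {}
    values = sc.values
    for t in types:
        in_idx = [col_of[c] for c in ann.cells_of_type(t) if c in col_of]
        out_idx = [i for i in range(sc.n_columns) if i not in set(in_idx)]
        if not in_idx or not out_idx:
            logger.warning("type %r has no in/out cells; skipped", t)
            continue
        x = values[:, in_idx]
        y = values[:, out_idx]
        detected = (x > 0).mean(axis=1) >= MIN_DETECTION_FRACTION
        if not detected.any():
            logger.warning("type %r: no detected genes; skipped", t)
            continue
        xs, ys = x[detected], y[detected]
        res = stats.mannwhitneyu(xs, ys, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
        padj = stats.false_discovery_control(pvals, method="bh")
        log2fc = xs.mean(axis=1) - ys.mean(axis=1)  # data already in log2 space
        genes = np.array(sc.gene_ids)[detected]
        df = pd.DataFrame(
            {"gene": genes, "log2fc": log2fc, "pval": pvals, "padj": padj}
        )
        df = df[df["log2fc"] > 0].sort_values(
            ["padj", "log2fc", "gene"], ascending=[True, False, True]
        )
        if len(df) < min_markers:
            logger.warning(
                "type %r has %d qualifying markers (< %d); skipped",
                t, len(df), min_markers,
            )
            continue
        out[t] = df.head(max_markers).reset_index(drop=True)
    return out


# --------------------------------------------------------------------------
# confidence scores

#: spots sampled per class for classifier training
N_TRAIN_SPOTS = 50
#: default probability below which a mapped cell is flagged for removal
CONFIDENCE_THRESHOLD = 0.10


@dataclass
class ConfidenceReport:
    """Per-cell mapping confidence plus per-type diagnostics."""

    cell_scores: dict[int, float]           # mapping-row sub_spot_index -> score
    spot_scores: dict[str, dict[str, float]]  # type -> spot_id -> probability
    markers: dict[str, list[str]]
    skipped_types: list[str]
    threshold: float = CONFIDENCE_THRESHOLD

    def flagged(self) -> list[int]:
        return [i for i, s in self.cell_scores.items() if s < self.threshold]


def scale_genes(values: np.ndarray) -> np.ndarray:
    """Per-gene z-score across columns (constant genes become zero)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


def train_spot_classifier(X: np.ndarray, y: np.ndarray):
    """Linear max-margin classifier with sigmoid-calibrated probabilities,
    the model behind per-type confidence scoring."""
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.svm import SVC

    clf = CalibratedClassifierCV(SVC(kernel="linear"), ensemble=False)
    clf.fit(X, y)
    return clf


def confidence_scores(
    mapping: MappingTable,
    sc_norm: ExpressionMatrix,
    st_norm: ExpressionMatrix,
    ann: CellAnnotation,
    seed: int = 0,
    markers: Optional[dict[str, pd.DataFrame]] = None,
    threshold: float = CONFIDENCE_THRESHOLD,
) -> ConfidenceReport:
    """Probability that each mapped cell's type belongs to its spot.

    Per type: 50 spots with at least one assigned cell of the type and
    50 without (sampled with replacement when scarce) are reconstituted
    as pseudo-bulks by averaging the normalized-and-scaled profiles of
    all cells assigned to the spot.  A linear SVM with calibrated
    probabilities, trained on the type's marker genes, then scores
    every spot of the normalized-and-scaled spatial matrix, and each
    mapped cell inherits its spot's probability.  Types mapped to no
    spot or to every spot are skipped and flagged.
    """
    if sc_norm.layer != "log2cpm" or st_norm.layer != "log2cpm":
        raise ValueError("confidence_scores expects log2cpm matrices")
    if markers is None:
        markers = find_markers(sc_norm, ann)

    rng = np.random.default_rng(seed)
    sc_scaled = scale_genes(sc_norm.values)
    st_scaled = scale_genes(st_norm.values)
    sc_col = {c: i for i, c in enumerate(sc_norm.column_ids)}
    gene_of = {g: i for i, g in enumerate(sc_norm.gene_ids)}
    st_gene_of = {g: i for i, g in enumerate(st_norm.gene_ids)}
    spot_ids = list(st_norm.column_ids)

    # spot -> member pool-cell source profiles (normalized+scaled sc columns)
    members: dict[str, list[int]] = {}
    types_in_spot: dict[str, set[str]] = {s: set() for s in spot_ids}
    for r in mapping.rows:
        if r.query_cell_id in sc_col:
            members.setdefault(r.assigned_spot_id, []).append(sc_col[r.query_cell_id])
        types_in_spot.setdefault(r.assigned_spot_id, set()).add(r.cell_type)

    pseudobulk: dict[str, np.ndarray] = {
        s: sc_scaled[:, idx].mean(axis=1) for s, idx in members.items()
    }

    cell_scores: dict[int, float] = {}
    spot_scores: dict[str, dict[str, float]] = {}
    used_markers: dict[str, list[str]] = {}
    skipped: list[str] = []
    mapped_types = sorted({r.cell_type for r in mapping.rows})
    for t in mapped_types:
        if t not in markers:
            skipped.append(t)
            continue
        pos = sorted(s for s in pseudobulk if t in types_in_spot.get(s, set()))
        neg = sorted(s for s in spot_ids if t not in types_in_spot.get(s, set())
                     and s in pseudobulk)
        # spots with no assigned cells at all cannot form a pseudo-bulk;
        # negatives therefore come from mapped spots lacking the type
        if not pos or not neg:
            logger.warning(
                "type %r mapped to %s; confidence undefined",
                t, "no spots" if not pos else "all spots",
            )
            skipped.append(t)
            continue
        genes = [g for g in markers[t]["gene"] if g in gene_of and g in st_gene_of]
        if len(genes) < MIN_MARKERS:
            skipped.append(t)
            continue
        used_markers[t] = genes
        g_sc = [gene_of[g] for g in genes]
        g_st = [st_gene_of[g] for g in genes]

        def draw(spots: list[str]) -> list[str]:
            if len(spots) >= N_TRAIN_SPOTS:
                take = rng.choice(len(spots), size=N_TRAIN_SPOTS, replace=False)
            else:
                take = rng.integers(0, len(spots), size=N_TRAIN_SPOTS)
            return [spots[i] for i in take]

        train_pos = draw(pos)
        train_neg = draw(neg)
        X = np.stack(
            [pseudobulk[s][g_sc] for s in train_pos]
            + [pseudobulk[s][g_sc] for s in train_neg]
        )
        y = np.array([1] * N_TRAIN_SPOTS + [0] * N_TRAIN_SPOTS)
        clf = train_spot_classifier(X, y)
        probs = clf.predict_proba(st_scaled[g_st, :].T)[:, list(clf.classes_).index(1)]
        spot_scores[t] = dict(zip(spot_ids, map(float, probs)))

    for r in mapping.rows:
        if r.cell_type in spot_scores and r.assigned_spot_id in spot_scores[r.cell_type]:
            cell_scores[r.sub_spot_index] = spot_scores[r.cell_type][r.assigned_spot_id]

    return ConfidenceReport(
        cell_scores=cell_scores,
        spot_scores=spot_scores,
        markers=used_markers,
        skipped_types=sorted(set(skipped)),
        threshold=threshold,
    )


# --------------------------------------------------------------------------
# near/far partition and fold-change ranking

def partition_by_tumor_distance(
    mapping: MappingTable,
    geometry: SpotGeometry,
    tumor_type: str,
    k: int = 5,
    tumor_region_spots: Optional[set[str]] = None,
) -> dict[int, str]:
    """Median-split each non-tumor cell type into 'close'/'far' groups
    by mean distance to the k nearest mapped tumor cells.

    Cells mapped inside a supplied tumor-region spot set get distance
    zero.  The split is rank-based within each type, so group sizes
    differ by at most one and ties at the median go to 'close'.
    Returns mapping-row sub_spot_index -> group.
    """
    tumor_rows = [r for r in mapping.rows if r.cell_type == tumor_type]
    if len(tumor_rows) < k:
        raise ValueError(
            f"fewer than k={k} mapped tumor cells ({len(tumor_rows)})"
        )
    tumor_xy = np.array(
        [geometry.coords[r.assigned_spot_id] for r in tumor_rows], dtype=float
    )
    by_type: dict[str, list[tuple[int, float]]] = {}
    for r in mapping.rows:
        if r.cell_type == tumor_type:
            continue
        if tumor_region_spots and r.assigned_spot_id in tumor_region_spots:
            dist = 0.0
        else:
            xy = np.array(geometry.coords[r.assigned_spot_id], dtype=float)
            d = np.linalg.norm(tumor_xy - xy[None, :], axis=1)
            dist = float(np.sort(d)[:k].mean())
        by_type.setdefault(r.cell_type, []).append((r.sub_spot_index, dist))
    out: dict[int, str] = {}
    for t, pairs in by_type.items():
        pairs.sort(key=lambda p: (p[1], p[0]))
        n_close = int(np.ceil(len(pairs) / 2))
        for rank, (idx, _) in enumerate(pairs):
            out[idx] = "close" if rank < n_close else "far"
    return out


MIN_GROUP_CELLS = 10
FOLD_CHANGE_PSEUDOCOUNT = 1.0


def rank_genes_by_fold_change(
    expr: ExpressionMatrix,
    groups: Mapping[str, str],
    pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2 fold change of mean normalized expression, close vs far.

    ``groups`` maps column ids of *expr* to 'close' or 'far'; both
    groups must contain at least ten cells.  Output is sorted by
    descending log2FC, the two-column shape expected by pre-ranked GSEA
    tools.
    """
    col_of = {c: i for i, c in enumerate(expr.column_ids)}
    close = [col_of[c] for c, g in groups.items() if g == "close" and c in col_of]
    far = [col_of[c] for c, g in groups.items() if g == "far" and c in col_of]
    if len(close) < MIN_GROUP_CELLS or len(far) < MIN_GROUP_CELLS:
        raise ValueError(
            f"both groups need >= {MIN_GROUP_CELLS} cells "
            f"(close={len(close)}, far={len(far)})"
        )
    mc = expr.values[:, close].mean(axis=1)
    mf = expr.values[:, far].mean(axis=1)
    log2fc = np.log2((mc + pseudocount) / (mf + pseudocount))
    df = pd.DataFrame({"gene": expr.gene_ids, "log2fc": log2fc})
    return df.sort_values(
        ["log2fc", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# retention index

def _corr_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson among columns; constant columns correlate 0."""
    from .assign import _standardize_columns

    z = _standardize_columns(values)
    return (z.T @ z) / values.shape[0]


def retention_index(
    query: ExpressionMatrix, reference: ExpressionMatrix
) -> float:
    """Preservation of cell–cell correlation structure after mapping.

    Both matrices must cover the same ordered cell set (query cells in
    the order of their assigned reference cells).  Q and R are the
    pairwise Pearson correlation matrices of query and reference
    columns; the index is the Pearson correlation between their upper
    triangles — 1 when transcriptomic structure is perfectly retained.
    """
    if query.n_columns != reference.n_columns:
        raise ValueError("query and reference must have the same column count")
    n = query.n_columns
    if n < 3:
        raise ValueError("need at least 3 cells")
    q = _corr_matrix(query.values)
    r = _corr_matrix(reference.values)
    iu = np.triu_indices(n, k=1)
    return _pearson(q[iu], r[iu]).r


def subsample_per_type(
    ann: CellAnnotation,
    cell_ids: Sequence[str],
    n: int = 150,
    seed: int = 0,
) -> list[str]:
    """Equal-size per-type subsample (without replacement) of cell ids,
    used to put cell types on a common footing before the retention
    index.  Types with fewer than n cells are dropped."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    by_type: dict[str, list[str]] = {}
    for c in cell_ids:
        by_type.setdefault(ann[c], []).append(c)
    for t in sorted(by_type):
        cells = sorted(by_type[t])
        if len(cells) < n:
            continue
        take = rng.choice(len(cells), size=n, replace=False)
        out.extend(cells[i] for i in sorted(take))
    return out
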