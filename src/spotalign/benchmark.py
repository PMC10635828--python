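"""Reproducible benchmarking experiments on simulated tissues.

These drive the whole pipeline end to end under controlled conditions:
precision versus expression noise, balanced assignment versus the
per-cell argmax baseline, exact-versus-integer solver agreement,
cells-per-spot estimator recovery, and the planted-error probe of the
confidence scores.  Both the test suite and the reproduction script
call these functions, so reported numbers always come from the same
code path as the library itself.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from .assign import (
    baseline_argmax,
    build_cost_matrix,
    pairwise_cost,
    solve_bruteforce,
    solve_exact,
    solve_integer_approx,
)
from .preprocess import intersect_genes, log_normalize
from .sampling import sample_pool
from .simulate import plant_swapped_errors, simulate_tissue, truth_mapping
from .spot_model import (
    estimate_cells_per_spot,
    expand_subspots,
    spot_model_from_counts,
    type_targets_from_fractions,
)
from .types import ExpressionMatrix

#: study conditions for the simulated precision experiments
STUDY_N_TYPES = 5
STUDY_N_GENES = 300
STUDY_CELLS_PER_TYPE = 40   # 200 cells total
STUDY_MEAN_CELLS = 5


def _mapping_from_perm(pool, sm, assignment):
    from .assign import _mapping_from_assignment

    return _mapping_from_assignment(pool, sm, assignment)


def precision_vs_noise(
    noise_levels: Sequence[float] = (0.0, 0.05, 0.25),
    n_seeds: int = 10,
    seed0: int = 0,
    n_types: int = STUDY_N_TYPES,
    n_genes: int = STUDY_N_GENES,
    cells_per_type: int = STUDY_CELLS_PER_TYPE,
    mean_cells: float = STUDY_MEAN_CELLS,
    metric: str = "neg_pearson",
) -> pd.DataFrame:
    """Precision of balanced mapping and of the per-cell argmax baseline
    on the same simulated tissues and the same sampled pools.

    Returns one row per (seed, noise level) with columns
    ``balanced`` and ``baseline``.
    """
    records = []
    for i in range(n_seeds):
        seed = int(seed0 + i)
        for p in noise_levels:
            t = simulate_tissue(
                n_types=n_types, n_genes=n_genes,
                cells_per_type=cells_per_type, layout="blocks",
                target_mean_cells_per_spot=mean_cells,
                noise_p=p, seed=seed,
            )
            sc_g, st_g, _ = intersect_genes(
                log_normalize(t.query), log_normalize(t.spot_counts)
            )
            sm = spot_model_from_counts(t.true_cell_counts())
            targets = type_targets_from_fractions(t.true_fractions(), sm.L)
            pool = sample_pool(
                sc_g, t.annotation, targets, seed + 10_000, mode="generation"
            )
            cost = build_cost_matrix(pool, expand_subspots(st_g, sm), metric)
            balanced = _mapping_from_perm(pool, sm, solve_exact(cost))
            naive = baseline_argmax(pool, st_g, metric)
            records.append(
                {
                    "seed": seed,
                    "noise_p": p,
                    "balanced": ev.precision(balanced, t.truth).overall,
                    "baseline": ev.precision(naive, t.truth).overall,
                }
            )
    return pd.DataFrame(records)


def oracle_equivalence(
    sizes: Iterable[int] = range(2, 8),
    instances_per_case: int = 28,
    metrics: Sequence[str] = ("neg_pearson", "neg_spearman", "euclidean"),
    seed: int = 0,
) -> dict:
    """Exact solver versus exhaustive enumeration on random
    expression-derived cost matrices; also accumulates the worst dual
    residuals seen across all optima."""
    rng = np.random.default_rng(seed)
    n_instances = 0
    max_cost_gap = 0.0
    worst_reduced = np.inf       # most negative reduced cost, scaled by eps unit
    worst_duality_gap = 0.0
    for metric in metrics:
        for n in sizes:
            for _ in range(instances_per_case):
                a = rng.poisson(rng.gamma(2.0, 2.0, size=(12, n))).astype(float)
                b = rng.poisson(rng.gamma(2.0, 2.0, size=(12, n))).astype(float)
                d = pairwise_cost(a, b, metric)
                exact = solve_exact(d)
                brute = solve_bruteforce(d)
                max_cost_gap = max(
                    max_cost_gap, abs(exact.total_cost - brute.total_cost)
                )
                r = exact.reduced_costs(d)
                worst_reduced = min(worst_reduced, float(r.min()))
                worst_duality_gap = max(
                    worst_duality_gap,
                    abs(exact.u.sum() + exact.v.sum() - exact.total_cost),
                )
                n_instances += 1
    return {
        "n_instances": n_instances,
        "max_cost_gap": max_cost_gap,
        "min_reduced_cost": worst_reduced,
        "max_duality_gap": worst_duality_gap,
    }


def solver_agreement(
    n_instances: int = 100, k: int = 50, scale: int = 10**6, seed: int = 0
) -> float:
    """Mean fraction of identically assigned cells, exact vs integer-
    rounded solver, on random Gaussian cost matrices."""
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_instances):
        d = rng.normal(size=(k, k))
        e = solve_exact(d)
        a = solve_integer_approx(d, scale=scale)
        fractions.append(float(np.mean(e.perm == a.perm)))
    return float(np.mean(fractions))


def estimator_recovery(n_spots: int = 40, max_cells: int = 12, seed: int = 0) -> float:
    """Pearson r of estimated versus true cells per spot on a tissue
    whose log2 UMI totals are exactly affine in the true count, with
    the minimum-count spot holding one cell and the estimator anchored
    at the true mean."""
    rng = np.random.default_rng(seed)
    true = rng.integers(1, max_cells, size=n_spots)
    true[0] = 1
    u = 8.0 + 0.5 * (true - 1)
    totals = 2.0**u - 1.0
    st = ExpressionMatrix(
        np.stack([totals / 2, totals / 2]),
        ["g1", "g2"],
        [f"s{i}" for i in range(n_spots)],
        "raw",
    )
    sm = estimate_cells_per_spot(st, mean_cells=float(true.mean()))
    return ev.cells_per_spot_concordance(
        sm, dict(zip(st.column_ids, (int(c) for c in true)))
    ).r


def planted_error_aucs(
    n_seeds: int = 5,
    seed0: int = 0,
    n_types: int = 4,
    n_genes: int = 300,
    cells_per_type: int = 75,
    swap_fraction: float = 0.10,
) -> list[float]:
    """AUC of confidence scores for separating deliberately swapped
    cells from correctly placed ones on blocks-layout tissues."""
    from sklearn.metrics import roc_auc_score

    aucs = []
    for i in range(n_seeds):
        seed = int(seed0 + i)
        t = simulate_tissue(
            n_types=n_types, n_genes=n_genes, cells_per_type=cells_per_type,
            layout="blocks", target_mean_cells_per_spot=5, seed=seed,
        )
        corrupted, planted = plant_swapped_errors(
            truth_mapping(t), t.spot_geometry, t.annotation,
            fraction=swap_fraction, seed=seed + 50,
        )
        sc_g, st_g, _ = intersect_genes(
            log_normalize(t.query), log_normalize(t.spot_counts)
        )
        rep = ev.confidence_scores(corrupted, sc_g, st_g, t.annotation, seed=seed)
        idx = {r.sub_spot_index: r.query_cell_id for r in corrupted.rows}
        y = [0 if idx[k] in planted else 1 for k in rep.cell_scores]
        s = list(rep.cell_scores.values())
        aucs.append(float(roc_auc_score(y, s)))
    return aucs


def retention_null(
    n_seeds: int = 20, n_genes: int = 60, n_cells: int = 12, seed0: int = 0
) -> list[float]:
    """Retention index of a matrix against a column-permuted copy of
    itself; centered on zero when structure is destroyed."""
    out = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed0 + i)
        vals = rng.poisson(rng.gamma(2.0, 2.0, size=(n_genes, n_cells))).astype(float)
        q = ExpressionMatrix(
            vals, [f"g{j}" for j in range(n_genes)],
            [f"c{j}" for j in range(n_cells)], "raw",
        )
        perm = rng.permutation(n_cells)
        ref = ExpressionMatrix(
            vals[:, perm], list(q.gene_ids), list(q.column_ids), "raw"
        )
        out.append(ev.retention_index(q, ref))
    return out
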