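"""Exact solver for the balanced linear assignment problem.

Shortest-augmenting-path (Jonker–Volgenant style) solver for a square
cost matrix, maintaining dual potentials u (rows) and v (columns).  At
termination the duals are feasible — every reduced cost
``r_kl = d_kl - u_k - v_l`` is nonnegative up to rounding — and
complementary slackness holds on assigned edges, which certifies global
optimality of the returned permutation (strong duality:
``sum(u) + sum(v) == total cost``).

One augmentation per row, each a Dijkstra-like search over columns, for
O(n^3) total time.  The inner column scan is vectorized.
"""
from __future__ import annotations

import itertools

import numpy as np


def solve_lap(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve min-cost perfect matching on a square cost matrix.

    Returns
    -------
    perm
        ``perm[i]`` is the column assigned to row ``i``.
    u, v
        Dual potentials over rows and columns.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    n = cost.shape[0]
    INF = np.inf
    # column n is a virtual start column; p[j] = row matched to column j
    u = np.zeros(n + 1)
    v = np.zeros(n + 1)
    p = np.full(n + 1, -1, dtype=int)
    way = np.zeros(n + 1, dtype=int)

    for i in range(n):
        p[n] = i
        j0 = n
        minv = np.full(n + 1, INF)
        used = np.zeros(n + 1, dtype=bool)
        while True:
            used[j0] = True
            i0 = p[j0]
            cur = cost[i0, :] - u[i0] - v[:n]
            upd = (cur < minv[:n]) & ~used[:n]
            minv[:n][upd] = cur[upd]
            way[:n][upd] = j0
            masked = np.where(used[:n], INF, minv[:n])
            j1 = int(np.argmin(masked))
            delta = masked[j1]
            used_idx = np.flatnonzero(used)
            u[p[used_idx]] += delta
            v[used_idx] -= delta
            minv[~used] -= delta
            j0 = j1
            if p[j0] == -1:
                break
        # augment along the alternating path back to the virtual column
        while j0 != n:
            j1 = way[j0]
            p[j0] = p[j1]
            j0 = j1

    perm = np.empty(n, dtype=int)
    for j in range(n):
        perm[p[j]] = j
    return perm, u[:n], v[:n]


def solve_lap_bruteforce(
    cost: np.ndarray, max_n: int = 8
) -> tuple[np.ndarray, float]:
    """Exhaustive minimum over all n! permutations (test oracle).

    Ties are broken in favor of the lexicographically first permutation.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    n = cost.shape[0]
    if n > max_n:
        raise ValueError(f"brute force limited to n <= {max_n}, got {n}")
    rows = np.arange(n)
    best_perm: tuple[int, ...] | None = None
    best_cost = np.inf
    for perm in itertools.permutations(range(n)):
        c = float(cost[rows, perm].sum())
        if c < best_cost:  # strict: keeps the first (lex-smallest) tie
            best_cost = c
            best_perm = perm
    assert best_perm is not None
    return np.array(best_perm, dtype=int), best_cost
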