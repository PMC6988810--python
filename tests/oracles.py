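"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive (enumeration, double loops, Monte
Carlo) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# MIC oracles
# ---------------------------------------------------------------------------

def _mi_bits(cell_counts: np.ndarray) -> float:
    """Mutual information (bits) of a 2-D contingency table."""
    n = cell_counts.sum()
    if n == 0:
        return 0.0
    p = cell_counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _cut_positions(sorted_vals: np.ndarray) -> list[int]:
    """Positions (in sorted order) where a grid line may fall: only between
    distinct values (a line cannot separate tied points)."""
    return [i for i in range(1, len(sorted_vals)) if sorted_vals[i] != sorted_vals[i - 1]]


def _partitions(cuts: list[int], max_parts: int):
    """All ways to choose 0..max_parts-1 cut positions."""
    for k in range(0, max_parts):
        yield from itertools.combinations(cuts, k)


def _assign_bins(order: np.ndarray, chosen_cuts) -> np.ndarray:
    """Bin id per original point given cut positions in the sorted order."""
    n = len(order)
    bins_sorted = np.zeros(n, dtype=int)
    for c in chosen_cuts:
        bins_sorted[c:] += 1
    out = np.empty(n, dtype=int)
    out[order] = bins_sorted
    return out


def exhaustive_mic(x, y, budget: int) -> float:
    """Exact MIC: enumerate every grid over both axes with kx*ky <= budget.

    Feasible for small n / small budgets only; the normalization and the
    shape enumeration match the MIC definition, the maximization is a full
    search instead of equipartition + dynamic programming.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    ox = np.argsort(x, kind="mergesort")
    oy = np.argsort(y, kind="mergesort")
    cuts_x = _cut_positions(x[ox])
    cuts_y = _cut_positions(y[oy])
    best = 0.0
    for kx in range(2, budget // 2 + 1):
        for ky in range(2, budget // kx + 1):
            norm = np.log2(min(kx, ky))
            for cx in itertools.chain.from_iterable(
                itertools.combinations(cuts_x, k) for k in range(1, kx)
            ):
                bx = _assign_bins(ox, cx)
                nbx = len(cx) + 1
                for cy in itertools.chain.from_iterable(
                    itertools.combinations(cuts_y, k) for k in range(1, ky)
                ):
                    by = _assign_bins(oy, cy)
                    table = np.zeros((nbx, len(cy) + 1))
                    for i in range(n):
                        table[bx[i], by[i]] += 1
                    val = _mi_bits(table) / norm
                    if val > best:
                        best = val
    return best


def exhaustive_best_x_partition(x, y_rows, n_rows: int, max_cols: int) -> float:
    """Max MI (bits) over all x-axis partitions into <= max_cols columns,
    with the row assignment fixed: the quantity ApproxMaxMI's DP optimizes."""
    x = np.asarray(x, dtype=float)
    ox = np.argsort(x, kind="mergesort")
    cuts = _cut_positions(x[ox])
    best = 0.0
    n = len(x)
    for chosen in _partitions(cuts, max_cols):
        bx = _assign_bins(ox, chosen)
        table = np.zeros((len(chosen) + 1, n_rows))
        for i in range(n):
            table[bx[i], y_rows[i]] += 1
        best = max(best, _mi_bits(table))
    return best


def _rank_equipartition(sorted_vals: np.ndarray, k: int) -> np.ndarray:
    """Independently-coded version of the published greedy tie-respecting
    equipartition: walk tie runs in sorted order, opening a new group when
    adding the run would overshoot the per-group target at least as much as
    stopping short undershoots it; the target is re-spread over the
    remaining groups after each advance."""
    n = len(sorted_vals)
    runs: list[int] = []
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        runs.append(j - i)
        i = j
    groups = np.empty(n, dtype=int)
    pos = 0
    g = 0
    filled = 0
    placed = 0
    target = n / k
    for size in runs:
        if filled > 0 and g < k - 1 and (
            abs(filled + size - target) >= abs(filled - target)
        ):
            g += 1
            filled = 0
            target = (n - placed) / (k - g)
        groups[pos:pos + size] = g
        pos += size
        filled += size
        placed += size
    return groups


def reference_mic(x, y, budget: int) -> float:
    """Independently-coded ApproxMaxMI-style MIC reference.

    Same scheme as the MINE heuristic (equipartition one axis, optimize the
    other, both orientations, max over shapes within the budget) but with a
    separately written equipartition rule and a full exhaustive search over
    the free axis's cut positions instead of clumps + dynamic programming.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for xv, yv in ((x, y), (y, x)):
        n = len(xv)
        ox = np.argsort(xv, kind="mergesort")
        oy = np.argsort(yv, kind="mergesort")
        cuts = _cut_positions(xv[ox])
        for ky in range(2, budget // 2 + 1):
            max_kx = budget // ky
            if max_kx < 2:
                break
            rows_sorted = _rank_equipartition(yv[oy], ky)
            rows = np.empty(n, dtype=int)
            rows[oy] = rows_sorted
            for chosen in _partitions(cuts, max_kx):
                bx = _assign_bins(ox, chosen)
                tab = np.zeros((len(chosen) + 1, ky))
                for i in range(n):
                    tab[bx[i], rows[i]] += 1
                mi = _mi_bits(tab)
                # a partition with c columns is admissible for any shape
                # kx >= c; the normalization is smallest at kx = max(c, 2)
                kx = max(len(chosen) + 1, 2)
                val = mi / np.log2(min(kx, ky))
                if val > best:
                    best = val
    return best


# ---------------------------------------------------------------------------
# Graph topology oracles
# ---------------------------------------------------------------------------

def brute_force_clustering(adj: np.ndarray) -> float:
    """Mean local clustering by explicit triangle counting (degree<2 -> 0)."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        d = len(nbrs)
        if d < 2:
            vals.append(0.0)
            continue
        links = 0
        for a in range(d):
            for b in range(a + 1, d):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        vals.append(2.0 * links / (d * (d - 1)))
    return float(np.mean(vals)) if vals else float("nan")


def brute_force_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path length over connected ordered pairs via BFS."""
    n = adj.shape[0]
    total, count = 0, 0
    for s in range(n):
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        while queue:
            u = queue.pop(0)
            for v in np.flatnonzero(adj[u]):
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t in range(n):
            if t != s and dist[t] > 0:
                total += dist[t]
                count += 1
    return total / count if count else float("nan")


# ---------------------------------------------------------------------------
# Rarefaction oracle
# ---------------------------------------------------------------------------

def monte_carlo_rarefaction(counts, depth: int, n_draws: int, seed: int):
    """Richness mean and SE at one depth by repeated subsampling without
    replacement (read-level shuffling)."""
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=int)
    reads = np.repeat(np.arange(len(counts)), counts)
    rich = np.empty(n_draws)
    for i in range(n_draws):
        sub = rng.choice(reads, size=depth, replace=False)
        rich[i] = len(np.unique(sub))
    return rich.mean(), rich.std(ddof=1) / np.sqrt(n_draws)
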