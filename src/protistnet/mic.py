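"""Maximal information coefficient (MIC) and signed pairwise association.

MIC measures the strength of any (linear or not) functional relationship
between two variables as the maximal grid-normalized mutual information:

    MIC(x, y) = max over grid shapes (kx, ky), kx*ky <= B(n), kx, ky >= 2 of
                I*(x, y; kx, ky) / log2(min(kx, ky))

where ``I*`` is the largest mutual information achievable by drawing a
kx-by-ky grid over the scatter of (x, y), and ``B(n) = n**b`` (default
exponent 0.6) is the grid-resolution budget. ``I*`` is approximated with the
ApproxMaxMI heuristic: one axis is equipartitioned, and the other axis's
partition is optimized exactly by dynamic programming over *clump*
boundaries (maximal runs of consecutive points sharing a row; an optimal
partition never needs to cut inside a clump). Both axis orientations are
computed and the larger value kept. Partitions are rank-based, so MIC is
invariant under strictly monotone transforms of either variable.

Significance is assessed with an explicit permutation null: the observed MIC
is compared against MICs of row-shuffled copies, giving
``p = (1 + #{MIC_perm >= MIC_obs}) / (1 + n_permutations)``.

The sign convention for co-occurrence networks uses the *nonlinearity*
statistic ``MIC - r**2`` (MIC minus squared Pearson correlation): values
above 0.5 mark strongly non-linear relationships, treated as negative
(exclusion-like) associations; all others are positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class MicParams:
    """MIC estimation and edge-selection parameters.

    b_exponent : grid budget exponent; B(n) = max(n**b_exponent, 4).
    clumps_factor : ApproxMaxMI 'c' parameter; at most c*kx candidate
        superclumps are offered to the dynamic program.
    n_permutations : permutation-null size for p-values.
    p_threshold : edge-selection significance cut (raw, uncorrected).
    min_total_reads : OTU total-abundance filter applied upstream.
    seed : stage seed for permutations.
    """

    b_exponent: float = 0.6
    clumps_factor: int = 15
    n_permutations: int = 1000
    p_threshold: float = 0.01
    min_total_reads: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.b_exponent < 1.0:
            raise ValueError(f"b_exponent must be in (0,1), got {self.b_exponent}")
        if self.clumps_factor < 1:
            raise ValueError("clumps_factor must be >= 1")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")

    def budget(self, n: int) -> int:
        return max(int(np.floor(n ** self.b_exponent)), 4)


@dataclass
class MicResult:
    """Association statistics for one unordered OTU pair."""

    otu_a: str
    otu_b: str
    mic: float
    pearson_r: float
    nonlinearity: float
    p_value: float | None = None

    @property
    def sign(self) -> str:
        return edge_sign(self)


@njit(cache=True)
def _equipartition(sorted_vals, k):
    """Assign sorted values to k nearly equal groups, never splitting ties.

    Returns group ids (0..k-1) aligned with the sorted order.
    """
    n = sorted_vals.shape[0]
    rows = np.empty(n, dtype=np.int64)
    i = 0
    curr = 0
    in_curr = 0
    desired = n / k
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        s = j - i
        if in_curr != 0 and curr < k - 1:
            if abs(in_curr + s - desired) >= abs(in_curr - desired):
                curr += 1
                in_curr = 0
                desired = (n - i) / (k - curr)
        for t in range(i, j):
            rows[t] = curr
        in_curr += s
        i = j
    return rows


@njit(cache=True)
def _clump_boundaries(x_sorted, row_of_xsorted):
    """Candidate column boundaries: cumulative point counts at clump ends.

    A clump is a maximal run of consecutive points (in x order) lying in a
    single common row; points with tied x values are never separated. The
    returned array starts at 0 and ends at n.
    """
    n = x_sorted.shape[0]
    bounds = np.empty(n + 1, dtype=np.int64)
    bounds[0] = 0
    m = 0
    i = 0
    prev_pure_row = -2  # row id if previous clump is single-row, else -1
    while i < n:
        j = i + 1
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        # Row composition of this x-tie group
        pure = row_of_xsorted[i]
        for t in range(i + 1, j):
            if row_of_xsorted[t] != pure:
                pure = -1
                break
        if pure >= 0 and pure == prev_pure_row and m > 0:
            bounds[m] = j  # extend previous clump
        else:
            m += 1
            bounds[m] = j
        prev_pure_row = pure
        i = j
    return bounds[: m + 1]


@njit(cache=True)
def _coarsen(bounds, n, max_groups):
    """Merge clump boundaries into at most max_groups superclumps of near-equal mass."""
    m = bounds.shape[0] - 1
    if m <= max_groups:
        return bounds
    out = np.empty(max_groups + 1, dtype=np.int64)
    out[0] = 0
    g = 0
    in_curr = 0
    desired = n / max_groups
    for t in range(1, m + 1):
        s = bounds[t] - bounds[t - 1]
        if in_curr != 0 and g < max_groups - 1:
            if abs(in_curr + s - desired) >= abs(in_curr - desired):
                g += 1
                out[g] = bounds[t - 1]
                desired = (n - bounds[t - 1]) / (max_groups - g)
                in_curr = 0
        in_curr += s
    out[g + 1] = n
    return out[: g + 2]


@njit(cache=True)
def _optimize_axis(bounds, cum_rows, n, ky, h_q, max_cols):
    """Best normalized MI for each column count 2..max_cols (DP over boundaries).

    cum_rows[t, r] is the number of points in rows ``r`` among the first
    bounds[t] points (x-sorted). Minimizes the total conditional row entropy
    over partitions into at most ``l`` columns cut at the boundaries; the
    mutual information is then I = H(Q) - H(Q|P).
    """
    m = bounds.shape[0] - 1
    # cost[i][j]: (points in (i, j]) * H(row distribution within), in bits
    cost = np.zeros((m + 1, m + 1))
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            tot = bounds[j] - bounds[i]
            c = 0.0
            for r in range(ky):
                cnt = cum_rows[j, r] - cum_rows[i, r]
                if cnt > 0:
                    c += cnt * np.log2(cnt)
            cost[i, j] = tot * np.log2(tot) - c
    inf = 1e300
    f = np.full((m + 1, max_cols + 1), inf)
    f[0, 0] = 0.0
    for j in range(1, m + 1):
        for l in range(1, max_cols + 1):
            best = inf
            for i in range(l - 1, j):
                v = f[i, l - 1] + cost[i, j]
                if v < best:
                    best = v
            f[j, l] = best
    out = np.zeros(max_cols + 1)
    running = inf
    for l in range(1, max_cols + 1):
        if f[m, l] < running:
            running = f[m, l]
        mi = h_q - running / n
        if mi < 0.0:
            mi = 0.0
        out[l] = mi
    return out


@njit(cache=True)
def _mic_one_orientation(x, y, budget, clumps_factor):
    """Max over shapes of normalized MI, with the y-axis equipartitioned."""
    n = x.shape[0]
    order_x = np.argsort(x, kind="mergesort")
    x_sorted = x[order_x]
    order_y = np.argsort(y, kind="mergesort")
    y_sorted = y[order_y]
    best = 0.0
    max_ky = budget // 2
    for ky in range(2, max_ky + 1):
        max_kx = budget // ky
        if max_kx < 2:
            break
        rows_sorted = _equipartition(y_sorted, ky)
        row_of = np.empty(n, dtype=np.int64)
        for t in range(n):
            row_of[order_y[t]] = rows_sorted[t]
        row_x = np.empty(n, dtype=np.int64)
        for t in range(n):
            row_x[t] = row_of[order_x[t]]
        # H(Q) over all points, bits
        counts = np.zeros(ky, dtype=np.int64)
        for t in range(n):
            counts[row_x[t]] += 1
        h_q = 0.0
        for r in range(ky):
            if counts[r] > 0:
                p = counts[r] / n
                h_q -= p * np.log2(p)
        bounds = _clump_boundaries(x_sorted, row_x)
        bounds = _coarsen(bounds, n, max(clumps_factor * max_kx, max_kx))
        m = bounds.shape[0] - 1
        cum = np.zeros((m + 1, ky), dtype=np.int64)
        pos = 0
        for t in range(1, m + 1):
            for r in range(ky):
                cum[t, r] = cum[t - 1, r]
            while pos < bounds[t]:
                cum[t, row_x[pos]] += 1
                pos += 1
        mis = _optimize_axis(bounds, cum, n, ky, h_q, max_kx)
        for kx in range(2, max_kx + 1):
            denom = np.log2(min(kx, ky))
            val = mis[kx] / denom
            if val > best:
                best = val
    return best


@njit(cache=True)
def _mic_stat(x, y, budget, clumps_factor):
    a = _mic_one_orientation(x, y, budget, clumps_factor)
    b = _mic_one_orientation(y, x, budget, clumps_factor)
    return a if a >= b else b


@njit(cache=True)
def _perm_count(x, y, budget, clumps_factor, observed, perms):
    """Count permuted MICs >= observed over precomputed permutation rows."""
    hits = 0
    for p in range(perms.shape[0]):
        yp = y[perms[p]]
        if _mic_stat(x, yp, budget, clumps_factor) >= observed - 1e-12:
            hits += 1
    return hits


def _as_float_vec(v, name):
    arr = np.ascontiguousarray(np.asarray(v, dtype=np.float64))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    return arr


def mic_statistic(x, y, params: MicParams | None = None) -> float:
    """MIC of two equal-length vectors (no p-value)."""
    params = params or MicParams()
    x = _as_float_vec(x, "x")
    y = _as_float_vec(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 8:
        raise ValueError(f"MIC needs n >= 8 points, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    return float(_mic_stat(x, y, params.budget(n), params.clumps_factor))


def compute_mic(x, y, params: MicParams | None = None,
                otu_a: str = "x", otu_b: str = "y") -> MicResult:
    """MIC, Pearson r and nonlinearity (MIC - r^2) for one pair."""
    params = params or MicParams()
    x = _as_float_vec(x, "x")
    y = _as_float_vec(y, "y")
    m = mic_statistic(x, y, params)
    if np.all(x == x[0]) or np.all(y == y[0]):
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return MicResult(otu_a=otu_a, otu_b=otu_b, mic=m, pearson_r=r,
                     nonlinearity=m - r * r)


def permutation_pvalue(x, y, params: MicParams | None = None,
                       observed: float | None = None,
                       rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for the MIC of a pair.

    p = (1 + #{MIC(x, shuffled y) >= MIC(x, y)}) / (1 + n_permutations).
    """
    params = params or MicParams()
    if params.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = _as_float_vec(x, "x")
    y = _as_float_vec(y, "y")
    n = x.shape[0]
    if observed is None:
        observed = mic_statistic(x, y, params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    perms = np.empty((params.n_permutations, n), dtype=np.int64)
    for i in range(params.n_permutations):
        perms[i] = rng.permutation(n)
    hits = int(_perm_count(x, y, params.budget(n), params.clumps_factor,
                           observed, perms))
    return (1 + hits) / (1 + params.n_permutations)


def edge_sign(result: MicResult) -> str:
    """negative iff nonlinearity (MIC - r^2) is strictly above 0.5, else positive."""
    return NEGATIVE if result.nonlinearity > 0.5 else POSITIVE


def build_edge_set(table, params: MicParams | None = None) -> list[MicResult]:
    """All-pairs MIC with permutation p-values; keep pairs with p < p_threshold.

    The table is expected to be rarefied and abundance-filtered upstream
    (``min_total_reads``); rows are OTUs, columns samples. Deterministic for
    a fixed ``params.seed``: each pair's permutations come from an
    independent child seed.
    """
    params = params or MicParams()
    counts = table.counts
    ids = list(counts.index)
    if len(ids) < 2:
        raise ValueError("need at least two OTUs to build an edge set")
    arr = counts.to_numpy(dtype=np.float64)
    n_pairs = len(ids) * (len(ids) - 1) // 2
    logger.info("build_edge_set: %d OTUs, %d pairs, %d permutations each",
                len(ids), n_pairs, params.n_permutations)
    root = np.random.SeedSequence(params.seed)
    results: list[MicResult] = []
    k = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            x, y = arr[i], arr[j]
            res = compute_mic(x, y, params, otu_a=ids[i], otu_b=ids[j])
            rng = np.random.default_rng(root.spawn(1)[0])
            res.p_value = permutation_pvalue(
                x, y, params, observed=res.mic, rng=rng
            )
            # p_threshold = 1.0 disables the filter (p is never above 1)
            if res.p_value < params.p_threshold or params.p_threshold >= 1.0:
                results.append(res)
            k += 1
    logger.info("build_edge_set: %d significant pairs of %d", len(results), n_pairs)
    return results
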