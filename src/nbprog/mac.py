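"""Maximal association coefficient (MAC).

MAC measures the (possibly nonlinear) association between two numeric
vectors by slicing the plane into a grid and taking an area-weighted mean of
the absolute Pearson correlation inside each cell: a nonlinear relationship
is approximated piecewise-linearly, and each piece is scored linearly.

Procedure for vectors x, y of length n:

1. A grid budget ``MG = max(4, floor(n^alpha))`` caps the number of cells
   (``alpha`` in [0, 1] is the resolution hyperparameter).
2. For every shape (s, t) with s in [2, MG/2] and t = floor(MG/s) >= 2
   (both orientations), x is split into s contiguous bins and y into t bins
   by exact 1-D k-means (dynamic programming, deterministic).
3. Within each grid cell holding at least ``min_cell_points`` points with
   variation in both coordinates, the absolute Pearson correlation |p_i| is
   computed; the association coefficient for the shape is the cell-area
   weighted average AC = sum_i w_i |p_i| with weights w_i normalised over
   the contributing cells (so sum w_i = 1).
4. MAC = the maximum AC over all shapes; it lies in [0, 1], is symmetric in
   its arguments, invariant to affine rescaling of either vector, and
   equals 1 for perfectly linear data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MacConfig",
    "GridPartition",
    "MacResult",
    "max_grid_count",
    "partition_1d",
    "association_coefficient",
    "mac",
    "grid_shapes",
]


@dataclass(frozen=True)
class MacConfig:
    """Hyperparameters of the MAC.

    alpha
        Grid-budget exponent in [0, 1]; larger alpha allows finer grids.
    min_cell_points
        Minimum points a cell needs for its Pearson correlation to count.
    count_invalid_cells
        If True, occupied cells that are too small / degenerate still enter
        the weight normalisation with contribution 0 (alternative weighting;
        the default excludes them entirely so a perfect line scores 1).
    rng_seed
        Reserved for stochastic partitioner fallbacks; the default exact
        1-D k-means is deterministic and ignores it.
    """

    alpha: float = 0.55
    min_cell_points: int = 2
    count_invalid_cells: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.min_cell_points < 2:
            raise ValueError("min_cell_points must be >= 2")


@dataclass
class GridPartition:
    """A realised s x t grid over a point set."""

    s: int
    t: int
    x_boundaries: np.ndarray
    y_boundaries: np.ndarray
    cell_assignments: np.ndarray  # (n, 2) of (x-bin, y-bin) indices


@dataclass
class MacResult:
    mac: float
    per_shape: list[tuple[int, int, float]]
    argmax_shape: tuple[int, int] | None


def max_grid_count(n: int, alpha: float) -> int:
    """Grid budget MG = max(4, floor(n^alpha))."""
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return max(4, int(np.floor(float(n) ** alpha)))


def grid_shapes(mg: int) -> list[tuple[int, int]]:
    """Grid shapes (s, t) with s in [2, MG/2], t = floor(MG/s) >= 2, deduplicated."""
    shapes: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for s in range(2, mg // 2 + 1):
        t = mg // s
        if t < 2:
            continue
        if (s, t) not in seen:
            seen.add((s, t))
            shapes.append((s, t))
    return shapes


# ---------------------------------------------------------------------------
# exact 1-D k-means (dynamic programming)
# ---------------------------------------------------------------------------


def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Optimal contiguous k-clustering of a 1-D array by within-cluster SS.

    Returns (labels, sorted cluster means). Labels are ordered along the
    real line (bin 0 = lowest interval). If the data have fewer than k
    distinct values, the effective k is reduced accordingly. Deterministic:
    the DP breaks cost ties toward the smallest split index.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        raise ValueError("empty input")
    k_eff = min(int(k), len(np.unique(v)))
    if k_eff < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(v, kind="stable")
    sv = v[order]
    if k_eff == 1:
        return np.zeros(n, dtype=int), np.array([sv.mean()])

    ps = np.concatenate(([0.0], np.cumsum(sv)))
    ps2 = np.concatenate(([0.0], np.cumsum(sv * sv)))

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-cluster SS of sv[i..j] (inclusive), vectorised over start i
        cnt = j - i + 1
        s = ps[j + 1] - ps[i]
        s2 = ps2[j + 1] - ps2[i]
        return np.maximum(s2 - s * s / cnt, 0.0)

    idx = np.arange(n)
    D = np.empty((k_eff, n))
    B = np.zeros((k_eff, n), dtype=int)
    # first row: cost of one cluster covering sv[0..j]
    cnt = idx + 1
    s = ps[1:] - ps[0]
    s2 = ps2[1:] - ps2[0]
    D[0] = np.maximum(s2 - s * s / cnt, 0.0)
    for q in range(1, k_eff):
        D[q], B[q] = np.inf, 0
        for j in range(q, n):
            starts = np.arange(q, j + 1)
            cost = D[q - 1][starts - 1] + seg_cost(starts, j)
            b = int(np.argmin(cost))
            D[q, j] = cost[b]
            B[q, j] = starts[b]

    labels_sorted = np.empty(n, dtype=int)
    j = n - 1
    for q in range(k_eff - 1, -1, -1):
        start = B[q, j] if q > 0 else 0
        labels_sorted[start : j + 1] = q
        j = start - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    means = np.array([sv[labels_sorted == q].mean() for q in range(k_eff)])
    return labels, means


def partition_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Cluster a numeric vector into up to ``k`` contiguous bins.

    Bins are the globally optimal within-cluster sum-of-squares 1-D
    clustering (exact, deterministic); with fewer distinct values than
    ``k``, fewer bins are produced.
    """
    labels, _ = _kmeans_1d(values, k)
    return labels


def _boundaries(values: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Bin edges: midpoints between consecutive cluster means, capped by
    the data range."""
    v = np.asarray(values, dtype=float)
    if means.size == 1:
        return np.array([v.min(), v.max()])
    mid = (means[:-1] + means[1:]) / 2.0
    return np.concatenate(([v.min()], mid, [v.max()]))


def _partition_with_widths(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels, means = _kmeans_1d(values, k)
    edges = _boundaries(values, means)
    return labels, edges, np.diff(edges)


def _ac_from_partitions(
    x: np.ndarray,
    y: np.ndarray,
    lx: np.ndarray,
    wx: np.ndarray,
    ly: np.ndarray,
    wy: np.ndarray,
    cfg: MacConfig,
) -> float:
    """Area-weighted mean |Pearson| over grid cells, given 1-D partitions."""
    nx, ny = wx.size, wy.size
    cell = lx * ny + ly
    ncell = nx * ny
    cnt = np.bincount(cell, minlength=ncell).astype(float)
    sx = np.bincount(cell, weights=x, minlength=ncell)
    sy = np.bincount(cell, weights=y, minlength=ncell)
    sxx = np.bincount(cell, weights=x * x, minlength=ncell)
    syy = np.bincount(cell, weights=y * y, minlength=ncell)
    sxy = np.bincount(cell, weights=x * y, minlength=ncell)
    # exact degeneracy detection per cell via min == max
    minx = np.full(ncell, np.inf)
    maxx = np.full(ncell, -np.inf)
    miny = np.full(ncell, np.inf)
    maxy = np.full(ncell, -np.inf)
    np.minimum.at(minx, cell, x)
    np.maximum.at(maxx, cell, x)
    np.minimum.at(miny, cell, y)
    np.maximum.at(maxy, cell, y)

    area = np.repeat(wx, ny) * np.tile(wy, nx)
    occupied = cnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(occupied, sx / np.maximum(cnt, 1), 0.0)
        my = np.where(occupied, sy / np.maximum(cnt, 1), 0.0)
        varx = sxx / np.maximum(cnt, 1) - mx * mx
        vary = syy / np.maximum(cnt, 1) - my * my
        cov = sxy / np.maximum(cnt, 1) - mx * my
    valid = (
        (cnt >= cfg.min_cell_points)
        & (minx < maxx)
        & (miny < maxy)
        & (area > 0)
    )
    abs_p = np.zeros(ncell)
    if valid.any():
        denom = np.sqrt(np.maximum(varx[valid], 0.0) * np.maximum(vary[valid], 0.0))
        abs_p[valid] = np.clip(np.abs(cov[valid]) / np.maximum(denom, 1e-300), 0.0, 1.0)
    weight_base = (occupied & (area > 0)) if cfg.count_invalid_cells else valid
    total_area = area[weight_base].sum()
    if total_area <= 0:
        return 0.0
    return float((area[valid] * abs_p[valid]).sum() / total_area)


def association_coefficient(
    x: np.ndarray,
    y: np.ndarray,
    s: int,
    t: int,
    cfg: MacConfig | None = None,
) -> tuple[float, GridPartition]:
    """AC for one grid shape: x split into s bins, y into t bins.

    Returns the coefficient and the realised :class:`GridPartition`. Cells
    with fewer than ``cfg.min_cell_points`` points, zero spread in either
    coordinate, or zero area do not contribute; AC = 0 when no cell
    qualifies.
    """
    cfg = cfg or MacConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if s < 2 or t < 2:
        raise ValueError("s and t must be >= 2")
    lx, ex, wx = _partition_with_widths(x, s)
    ly, ey, wy = _partition_with_widths(y, t)
    ac = _ac_from_partitions(x, y, lx, wx, ly, wy, cfg)
    part = GridPartition(
        s=wx.size,
        t=wy.size,
        x_boundaries=ex,
        y_boundaries=ey,
        cell_assignments=np.column_stack([lx, ly]),
    )
    return ac, part


def _canonical_order(a: np.ndarray, b: np.ndarray) -> bool:
    """True if a sorts strictly before b (lexicographic on values)."""
    for u, v in zip(a, b):
        if u != v:
            return bool(u < v)
    return False


class _PartitionCache:
    """Memoised 1-D partitions of a fixed vector for several bin counts."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float).ravel()
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def get(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if k not in self._cache:
            labels, _, widths = _partition_with_widths(self.values, k)
            self._cache[k] = (labels, widths)
        return self._cache[k]


def _mac_cached(
    cx: _PartitionCache, cy: _PartitionCache, cfg: MacConfig
) -> MacResult:
    # canonical argument order: AC(x,y,s,t) = AC(y,x,t,s) holds exactly in
    # real arithmetic but not under floating summation order, so evaluate
    # every pair in a fixed order to make mac(x, y) == mac(y, x) exact
    swapped = _canonical_order(cy.values, cx.values)
    if swapped:
        inner = _mac_cached(cy, cx, cfg)
        return MacResult(
            inner.mac,
            [(b, a, v) for a, b, v in inner.per_shape],
            None if inner.argmax_shape is None else inner.argmax_shape[::-1],
        )
    x, y = cx.values, cy.values
    n = x.size
    if n < 4:
        raise ValueError("MAC needs at least 4 points (2x2 grid structure)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MacResult(0.0, [], None)
    mg = max_grid_count(n, cfg.alpha)
    evals: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()
    for s, t in grid_shapes(mg):
        for a, b in ((s, t), (t, s)):  # both orientations -> exact symmetry
            if (a, b) in seen:
                continue
            seen.add((a, b))
            lx, wx = cx.get(a)
            ly, wy = cy.get(b)
            evals.append((a, b, _ac_from_partitions(x, y, lx, wx, ly, wy, cfg)))
    if not evals:
        return MacResult(0.0, [], None)
    best = max(range(len(evals)), key=lambda i: evals[i][2])
    a, b, value = evals[best]
    return MacResult(float(value), evals, (a, b))


def mac(x: np.ndarray, y: np.ndarray, cfg: MacConfig | None = None) -> MacResult:
    """Maximal association coefficient between two numeric vectors.

    Enumerates every admissible grid shape (both orientations, so the
    result is exactly symmetric in x and y) and returns the maximum AC
    together with the full per-shape table. A constant input vector yields
    MAC = 0 by convention.
    """
    cfg = cfg or MacConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return _mac_cached(_PartitionCache(x), _PartitionCache(y), cfg)


def pairwise_mac(X: np.ndarray, cfg: MacConfig | None = None) -> np.ndarray:
    """Symmetric matrix of MAC values between all column pairs of X.

    Shares the 1-D partition work across pairs: each column is partitioned
    once per bin count instead of once per pair.
    """
    cfg = cfg or MacConfig()
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    caches = [_PartitionCache(X[:, j]) for j in range(d)]
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            out[i, j] = out[j, i] = _mac_cached(caches[i], caches[j], cfg).mac
    return out
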