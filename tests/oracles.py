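"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive and written against the mathematical definitions only:
the grid-association oracle enumerates every contiguous 1-D partition
exhaustively (no dynamic programming) and recomputes the area-weighted
absolute-Pearson sum cell by cell with plain Python loops; the AUC oracle
enumerates every positive-negative pair. Feasible for n <= ~30.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def best_contiguous_partition(values, k):
    """Exhaustive optimal within-cluster-SS split of sorted values into
    <= k contiguous groups. Returns labels in original order."""
    v = np.asarray(values, dtype=float)
    n = v.size
    k = min(k, len(set(v.tolist())))
    order = np.argsort(v, kind="stable")
    sv = v[order]
    if k == 1:
        return np.zeros(n, dtype=int), np.array([sv.mean()])
    best_cost, best_labels = math.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        cost = 0.0
        labels_sorted = np.empty(n, dtype=int)
        for g in range(k):
            seg = sv[bounds[g] : bounds[g + 1]]
            cost += float(((seg - seg.mean()) ** 2).sum())
            labels_sorted[bounds[g] : bounds[g + 1]] = g
        if cost < best_cost - 1e-15:
            best_cost, best_labels = cost, labels_sorted.copy()
    labels = np.empty(n, dtype=int)
    labels[order] = best_labels
    means = np.array([sv[best_labels == g].mean() for g in range(k)])
    return labels, means


def _edges(values, means):
    v = np.asarray(values, dtype=float)
    if means.size == 1:
        return np.array([v.min(), v.max()])
    mids = [(means[i] + means[i + 1]) / 2 for i in range(means.size - 1)]
    return np.array([v.min(), *mids, v.max()])


def brute_ac(x, y, s, t, min_cell_points=2):
    """Association coefficient for one grid shape, cell by cell."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lx, mx = best_contiguous_partition(x, s)
    ly, my = best_contiguous_partition(y, t)
    ex, ey = _edges(x, mx), _edges(y, my)
    contributions = []  # (area, |pearson|)
    for i in range(mx.size):
        for j in range(my.size):
            inside = (lx == i) & (ly == j)
            area = (ex[i + 1] - ex[i]) * (ey[j + 1] - ey[j])
            if inside.sum() < min_cell_points or area <= 0:
                continue
            cx, cy = x[inside], y[inside]
            if cx.min() == cx.max() or cy.min() == cy.max():
                continue
            r = np.corrcoef(cx, cy)[0, 1]
            contributions.append((area, abs(r)))
    if not contributions:
        return 0.0
    total = sum(a for a, _ in contributions)
    return sum(a * p for a, p in contributions) / total


def brute_mac(x, y, alpha=0.55, min_cell_points=2):
    """Max over all admissible grid shapes (both orientations) of brute_ac."""
    n = len(x)
    mg = max(4, math.floor(n**alpha))
    best = 0.0
    for s in range(2, mg // 2 + 1):
        t = mg // s
        if t < 2:
            continue
        for a, b in ((s, t), (t, s)):
            best = max(best, brute_ac(x, y, a, b, min_cell_points))
    return best


def brute_auc(scores, labels):
    """Pairwise Mann-Whitney AUC: ordered pairs count 1, ties 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_fisher(x, y):
    """Fisher score of one feature, population-variance convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    mu = x.mean()
    num = den = 0.0
    for cls in np.unique(y):
        sub = x[y == cls]
        num += len(sub) * (sub.mean() - mu) ** 2
        den += len(sub) * float(np.mean((sub - sub.mean()) ** 2))
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den
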