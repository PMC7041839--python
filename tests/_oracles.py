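"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library paths they check: hulls by exhaustive
edge testing, graph metrics by direct edge/triangle enumeration, permutation
p-values by full enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """Convex-hull vertex set by exhaustive point-in-triangle elimination.

    A point is interior iff it lies inside (or on) a triangle of three other
    points without being a vertex of the hull; O(n^4), fine for n <= 12.
    """
    pts = [tuple(p) for p in np.unique(np.asarray(points, dtype=float), axis=0)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def in_triangle(p, a, b, c):
        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        has_neg = (d1 < -1e-12) or (d2 < -1e-12) or (d3 < -1e-12)
        has_pos = (d1 > 1e-12) or (d2 > 1e-12) or (d3 > 1e-12)
        return not (has_neg and has_pos)

    hull = set()
    for p in pts:
        others = [q for q in pts if q != p]
        interior = any(
            in_triangle(p, a, b, c) for a, b, c in itertools.combinations(others, 3)
        )
        if not interior:
            hull.add(p)
    return hull


def shoelace_area(vertices) -> float:
    """Polygon area from an ordered vertex list."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def graph_metrics_bruteforce(adj: np.ndarray) -> dict:
    """Density, normalized degree, local clustering by direct enumeration."""
    n = adj.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    density = len(edges) / (n * (n - 1) / 2)
    deg = adj.sum(axis=1)
    k = deg / (n - 1)
    clustering = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        clustering[v] = 2 * links / (len(nbrs) * (len(nbrs) - 1))
    return {"density": density, "k": k, "clustering": clustering}


def qap_exhaustive_p(Y: np.ndarray, X: np.ndarray) -> float:
    """Single-predictor QAP p-value over all n! simultaneous permutations.

    The statistic is |slope| of the off-diagonal regression of y on x; each
    permutation relabels X's rows and columns together.
    """
    n = Y.shape[0]
    mask = ~np.eye(n, dtype=bool)
    y = Y[mask]

    def slope(xv):
        xc = xv - xv.mean()
        return float(xc @ (y - y.mean()) / (xc @ xc))

    b_obs = abs(slope(X[mask]))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = list(perm)
        b = abs(slope(X[np.ix_(p, p)][mask]))
        total += 1
        if b >= b_obs - 1e-12:
            count += 1
    return count / total
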