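"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's analytic formulas: the
possibility degree is found by grid search over membership functions, and
the extent-analysis micro-evaluation works on raw float triples.
"""

from __future__ import annotations

import numpy as np


def tri_membership(x: np.ndarray, l: float, m: float, u: float) -> np.ndarray:
    """Triangular membership evaluated by linear interpolation."""
    return np.interp(x, [l, m, u], [0.0, 1.0, 0.0], left=0.0, right=0.0)


def grid_possibility(t1, t2, n_grid: int = 60_000) -> float:
    """V(t1 >= t2) by brute force: 1 if the first mode dominates, else the
    maximum of min(membership1, membership2) found by a two-stage grid search."""
    l1, m1, u1 = tuple(t1)
    l2, m2, u2 = tuple(t2)
    if m1 >= m2:
        return 1.0
    lo, hi = min(l1, l2), max(u1, u2)
    xs = np.linspace(lo, hi, n_grid)
    vals = np.minimum(tri_membership(xs, l1, m1, u1), tri_membership(xs, l2, m2, u2))
    k = int(np.argmax(vals))
    # refine around the coarse optimum
    a, b = xs[max(k - 2, 0)], xs[min(k + 2, n_grid - 1)]
    xs2 = np.linspace(a, b, n_grid)
    vals2 = np.minimum(tri_membership(xs2, l1, m1, u1), tri_membership(xs2, l2, m2, u2))
    return float(max(vals.max(), vals2.max()))


def brute_extent_weights(grid: list[list[tuple[float, float, float]]]) -> list[float]:
    """Extent analysis on raw (l, m, u) triples using only float loops and the
    grid-search possibility oracle; returns sum-normalized weights."""
    n = len(grid)
    gl = sum(c[0] for row in grid for c in row)
    gm = sum(c[1] for row in grid for c in row)
    gu = sum(c[2] for row in grid for c in row)
    extents = []
    for row in grid:
        rl = sum(c[0] for c in row)
        rm = sum(c[1] for c in row)
        ru = sum(c[2] for c in row)
        extents.append((rl / gu, rm / gm, ru / gl))
    wprime = []
    for i in range(n):
        vs = [grid_possibility(extents[i], extents[k]) for k in range(n) if k != i]
        wprime.append(min(vs))
    total = sum(wprime)
    return [w / total for w in wprime]


def random_tfn(rng: np.random.Generator, lo: float = 0.1, hi: float = 6.0,
               min_gap: float = 0.2, max_gap: float = 4.0):
    """A random well-separated positive (l, m, u) triple for oracle tests."""
    l = rng.uniform(lo, hi)
    m = l + rng.uniform(min_gap, max_gap)
    u = m + rng.uniform(min_gap, max_gap)
    return (l, m, u)
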