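"""Independent brute-force oracles used to pin down expected values.

Each oracle recomputes a quantity by the most direct means available —
numerical quadrature, exhaustive enumeration, per-pixel loops — sharing
no code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def spheroid_area_quadrature(height_um: float, width_um: float) -> float:
    """Surface of revolution: S = 2π ∫ x(z) √(1 + x'(z)²) dz.

    The spheroid has polar semi-axis c = width/2 along z and equatorial
    semi-axis a = height/2, i.e. x(z) = a√(1 − z²/c²).
    """
    a = height_um / 2.0
    c = width_um / 2.0

    def integrand(z: float) -> float:
        u = 1.0 - (z * z) / (c * c)
        if u <= 0:
            return 0.0
        x = a * math.sqrt(u)
        dx = -a * z / (c * c * math.sqrt(u))
        return x * math.sqrt(1.0 + dx * dx)

    val, _ = quad(integrand, -c, c, limit=400, epsabs=1e-12, epsrel=1e-12)
    return 2.0 * math.pi * val


def max_feret_exhaustive(coords: np.ndarray) -> float:
    """O(n²) maximum pairwise distance between component pixel centers."""
    best = 0.0
    pts = np.asarray(coords, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            if d > best:
                best = d
    return best


def _boundary_distance(point, mask, pixel_size):
    """Distance from a μm point to false pixel centers and the frame edge."""
    h, w = mask.shape
    px = pixel_size
    x, y = point
    best = min(x + 0.5 * px, (w - 0.5) * px - x, y + 0.5 * px, (h - 0.5) * px - y)
    rows, cols = np.nonzero(~mask)
    for r, c in zip(rows, cols):
        best = min(best, math.dist((x, y), (c * px, r * px)))
    return best


def brute_F(points, mask, pixel_size, r_grid, correction="border", ref_step=1):
    """Per-pixel empty-space estimator by explicit loops."""
    points = np.asarray(points, dtype=float)
    refs, d_event, d_bound = [], [], []
    h, w = mask.shape
    for row in range(0, h, ref_step):
        for col in range(0, w, ref_step):
            if not mask[row, col]:
                continue
            ref = (col * pixel_size, row * pixel_size)
            refs.append(ref)
            d_event.append(min(math.dist(ref, p) for p in points))
            d_bound.append(_boundary_distance(ref, mask, pixel_size))
    out = []
    for r in r_grid:
        if correction == "none":
            out.append(np.mean([d <= r for d in d_event]))
        else:
            elig = [i for i, b in enumerate(d_bound) if b >= r]
            if not elig:
                out.append(np.nan)
            else:
                out.append(np.mean([d_event[i] <= r for i in elig]))
    return np.array(out)


def brute_K(points, mask, pixel_size, r_grid, correction="none"):
    """Pair-counting K estimator by explicit loops, all edge modes."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    area = mask.sum() * pixel_size**2
    d = np.array([[math.dist(p, q) for q in pts] for p in pts])
    out = []
    if correction == "translation":
        wx = mask.shape[1] * pixel_size
        wy = mask.shape[0] * pixel_size
    if correction == "border":
        b = [_boundary_distance(p, mask, pixel_size) for p in pts]
    for r in r_grid:
        if correction == "none":
            cnt = sum(
                1 for i in range(n) for j in range(n) if i != j and d[i, j] <= r
            )
            out.append(area / (n * (n - 1)) * cnt)
        elif correction == "border":
            kept = [i for i in range(n) if b[i] >= r]
            if not kept:
                out.append(np.nan)
                continue
            total = sum(
                1 for i in kept for j in range(n) if j != i and d[i, j] <= r
            )
            out.append(area / (n - 1) * total / len(kept))
        elif correction == "translation":
            s = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j or d[i, j] > r:
                        continue
                    dx = abs(pts[i, 0] - pts[j, 0])
                    dy = abs(pts[i, 1] - pts[j, 1])
                    s += area / ((wx - dx) * (wy - dy))
            out.append(area / (n * (n - 1)) * s)
    return np.array(out)


def brute_nn(points):
    """Nearest other-point distance, O(n²)."""
    pts = np.asarray(points, dtype=float)
    return np.array(
        [
            min(math.dist(p, q) for j, q in enumerate(pts) if j != i)
            for i, p in enumerate(pts)
        ]
    )


def brute_upgma(dist):
    """Naive UPGMA agglomeration on a full distance matrix.

    Returns the sequence of merge heights and the list of leaf-index sets
    merged at each step (lexicographically smallest pair on ties).
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    heights, merges = [], []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                val = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or val < best[0] - 1e-15:
                    best = (val, a, b)
        val, a, b = best
        heights.append(val)
        merges.append(clusters[a] | clusters[b])
        clusters[a] = clusters.pop(a) | clusters.pop(b)  # a < b by construction
    return np.array(heights), merges
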