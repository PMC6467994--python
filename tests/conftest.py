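"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths:
the minimum-enclosing-circle check enumerates all diameter and
circumscribed candidate circles; overlap areas come from Monte-Carlo
sampling; amalgamation is checked against a plain union-find over the
pairwise-proximity graph.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_mec(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest enclosing circle by exhaustive pair/triple enumeration.

    Every candidate circle is either the diameter circle of a point pair
    or the circumscribed circle of a point triple; the smallest candidate
    containing all points is the answer.  O(n^3) checks, n <= ~60.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    tol = 1e-9

    def contains_all(center, r):
        d = np.sqrt(((pts - center) ** 2).sum(axis=1))
        return np.all(d <= r * (1 + tol) + tol)

    best_c, best_r = pts[0], 0.0
    if n == 1:
        return best_c, best_r
    best_r = math.inf
    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2
            r = float(np.hypot(*(pts[i] - c)))
            if r < best_r and contains_all(c, r):
                best_c, best_r = c, r
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c3 = pts[i], pts[j], pts[k]
                d = 2 * (a[0] * (b[1] - c3[1]) + b[0] * (c3[1] - a[1])
                         + c3[0] * (a[1] - b[1]))
                if d == 0:
                    continue
                ux = ((a @ a) * (b[1] - c3[1]) + (b @ b) * (c3[1] - a[1])
                      + (c3 @ c3) * (a[1] - b[1])) / d
                uy = ((a @ a) * (c3[0] - b[0]) + (b @ b) * (a[0] - c3[0])
                      + (c3 @ c3) * (b[0] - a[0])) / d
                center = np.array([ux, uy])
                r = float(np.hypot(*(a - center)))
                if r < best_r and contains_all(center, r):
                    best_c, best_r = center, r
    return best_c, best_r


def mc_circle_intersection(c1, r1, c2, r2, n_samples: int, seed: int) -> float:
    """Monte-Carlo circle-overlap area: sample uniformly inside the
    smaller circle, count hits in the other."""
    if r2 < r1:
        c1, r1, c2, r2 = c2, r2, c1, r1
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 2_000_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        u = rng.random(m)
        theta = rng.random(m) * 2 * math.pi
        r = r1 * np.sqrt(u)
        x = c1[0] + r * np.cos(theta)
        y = c1[1] + r * np.sin(theta)
        hits += int(np.count_nonzero(
            (x - c2[0]) ** 2 + (y - c2[1]) ** 2 <= r2 * r2
        ))
        remaining -= m
    return math.pi * r1 * r1 * hits / n_samples


def mc_polygon_area(vertices: np.ndarray, n_samples: int, seed: int) -> float:
    """Monte-Carlo point-in-polygon area estimate (ray crossing, vectorized)."""
    v = np.asarray(vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.random((n_samples, 2)) * (hi - lo) + lo
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(n_samples, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y)) & (
            x < (x2 - x1) * (y - y1) / (y2 - y1) + x1
        )
        inside ^= crosses
    box_area = float(np.prod(hi - lo))
    return box_area * inside.mean()


def union_find_components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of an undirected graph (plain union-find)."""
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in edges:
        parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_star_polygon(rng, n_vertices: int, radius: float = 1.0) -> np.ndarray:
    """A random simple (star-shaped) polygon: sorted angles, jittered radii."""
    angles = np.sort(rng.uniform(0, 2 * math.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
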