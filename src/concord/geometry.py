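"""Exact planar geometry for annotation agreement.

Everything downstream — registration residuals, circumcircle Jaccard
indices, area comparisons — reduces to a handful of primitives on points,
simple polygons and circles in physical (mm) coordinates:

* shoelace polygon area,
* the minimum enclosing circle (the "circumcircle" drawn around an
  annotated lesion),
* the closed-form circular-lens intersection area, and
* the Jaccard index of two circles, J(A, B) = |A∩B| / |A∪B|.

The circle-based Jaccard index is the headline agreement statistic: two
graders' (or two modalities') lesion outlines are each replaced by the
smallest circle covering them, and overlap is measured between those
circles.  A raster-mask Jaccard is provided for cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely

from .errors import (
    EmptyInputError,
    InvalidCircleError,
    InvalidPolygonError,
    UndefinedRatioError,
)

__all__ = [
    "Point2D",
    "Polygon2D",
    "Circle",
    "polygon_area",
    "min_enclosing_circle",
    "circle_intersection_area",
    "circle_jaccard",
    "mask_jaccard",
]

#: relative tolerance for containment / circle-identity decisions
TOL = 1e-9

# fixed shuffle seed: Welzl's expected-linear behaviour needs a random
# permutation, but results must not depend on caller input order
_WELZL_SEED = 0x5EED


@dataclass(frozen=True)
class Point2D:
    """A point in the plane, physical units (mm) unless stated otherwise."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


class Polygon2D:
    """A simple closed polygon given by its ordered vertices.

    The last vertex connects implicitly back to the first.  Simplicity
    (no self-intersection) is required for area operations and is checked
    on construction via shapely.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Iterable[Point2D] | np.ndarray):
        if isinstance(vertices, np.ndarray):
            arr = np.asarray(vertices, dtype=float)
        else:
            pts = list(vertices)
            arr = np.array(
                [[p.x, p.y] if isinstance(p, Point2D) else tuple(p) for p in pts],
                dtype=float,
            ).reshape(-1, 2)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise InvalidPolygonError(
                f"polygon needs >=3 vertices, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidPolygonError("polygon has non-finite vertices")
        self.vertices = arr

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def is_simple(self) -> bool:
        ring = shapely.LinearRing(self.vertices)
        return bool(ring.is_simple) and self.to_shapely().is_valid

    @property
    def points(self) -> list[Point2D]:
        return [Point2D(x, y) for x, y in self.vertices]

    def __len__(self) -> int:
        return len(self.vertices)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Polygon2D) and np.array_equal(
            self.vertices, other.vertices
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Polygon2D({len(self.vertices)} vertices)"


@dataclass(frozen=True)
class Circle:
    """A circle: center plus non-negative radius (mm)."""

    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.radius) or self.radius < 0:
            raise InvalidCircleError(f"invalid radius {self.radius}")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def contains(self, p: Point2D, tol: float = TOL) -> bool:
        d = math.hypot(p.x - self.center.x, p.y - self.center.y)
        return d <= self.radius * (1.0 + tol) + tol


def polygon_area(poly: Polygon2D) -> float:
    """Absolute (orientation-independent) shoelace area of a simple polygon.

    Raises
    ------
    InvalidPolygonError
        if the polygon self-intersects.
    """
    if not poly.is_simple():
        raise InvalidPolygonError("polygon is self-intersecting")
    v = poly.vertices
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# minimum enclosing circle (Welzl)
# ---------------------------------------------------------------------------


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.hypot(*(p - c)))


def _circle_three(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, float] | None:
    """Circumscribed circle of a non-degenerate triangle, else None."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0.0:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(c: tuple[np.ndarray, float], p: np.ndarray) -> bool:
    center, r = c
    return float(np.hypot(*(p - center))) <= r * (1.0 + TOL) + TOL


def _circle_from_boundary(boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if not boundary:
        return np.zeros(2), 0.0
    if len(boundary) == 1:
        return boundary[0].copy(), 0.0
    if len(boundary) == 2:
        return _circle_two(boundary[0], boundary[1])
    c = _circle_three(*boundary)
    if c is not None:
        return c
    # collinear support: the smallest circle through the extreme pair
    best: tuple[np.ndarray, float] | None = None
    for i in range(3):
        for j in range(i + 1, 3):
            cand = _circle_two(boundary[i], boundary[j])
            if all(_in_circle(cand, p) for p in boundary):
                if best is None or cand[1] > best[1]:
                    best = cand
    assert best is not None
    return best


def min_enclosing_circle(points: Sequence[Point2D] | np.ndarray) -> Circle:
    """Smallest circle containing every input point (Welzl's algorithm).

    The result is deterministic and independent of the input ordering:
    points are deduplicated and sorted before an internally seeded
    shuffle.  Degenerate inputs (one point, collinear points) fall back
    to the 1-/2-point base cases.

    Raises
    ------
    EmptyInputError
        on an empty point list.
    """
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float).reshape(-1, 2)
    else:
        arr = np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
    if arr.shape[0] == 0:
        raise EmptyInputError("min_enclosing_circle of no points")
    arr = np.unique(arr, axis=0)  # dedupe + lexicographic sort
    rng = np.random.default_rng(_WELZL_SEED)
    order = rng.permutation(arr.shape[0])
    pts = [arr[i] for i in order]

    # iterative move-to-front Welzl
    center, radius = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        p = pts[i]
        if _in_circle((center, radius), p):
            continue
        center, radius = p.copy(), 0.0
        for j in range(i):
            q = pts[j]
            if _in_circle((center, radius), q):
                continue
            center, radius = _circle_two(p, q)
            for k in range(j):
                r_ = pts[k]
                if _in_circle((center, radius), r_):
                    continue
                center, radius = _circle_from_boundary([p, q, r_])
    return Circle(Point2D(float(center[0]), float(center[1])), float(radius))


# ---------------------------------------------------------------------------
# circle overlap and Jaccard index
# ---------------------------------------------------------------------------


def circle_intersection_area(a: Circle, b: Circle) -> float:
    """Closed-form area of the intersection of two circles (circular lens).

    Returns 0 for disjoint circles and pi*min(r)^2 when one circle
    contains the other; symmetric in its arguments.
    """
    r1, r2 = a.radius, b.radius
    d = math.hypot(b.center.x - a.center.x, b.center.y - a.center.y)
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    # circular-lens ("vesica") area
    alpha = math.acos(np.clip((d * d + r1 * r1 - r2 * r2) / (2 * d * r1), -1, 1))
    beta = math.acos(np.clip((d * d + r2 * r2 - r1 * r1) / (2 * d * r2), -1, 1))
    tri = 0.5 * math.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return r1 * r1 * alpha + r2 * r2 * beta - tri


def circle_jaccard(a: Circle, b: Circle) -> float:
    """Jaccard index J(A,B) = |A∩B| / (|A| + |B| − |A∩B|) of two circles.

    Symmetric, in [0, 1]; exactly 1 iff the circles coincide.

    Raises
    ------
    UndefinedRatioError
        if both radii are zero (the union is empty).
    """
    if a.radius == 0.0 and b.radius == 0.0:
        raise UndefinedRatioError("Jaccard index of two degenerate circles")
    inter = circle_intersection_area(a, b)
    union = a.area + b.area - inter
    return float(np.clip(inter / union, 0.0, 1.0))


def mask_jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Pixel-wise Jaccard index of two binary masks of identical shape.

    The raster alternative to :func:`circle_jaccard`, used to
    cross-validate the analytic circle overlap.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise UndefinedRatioError("Jaccard index of two empty masks")
    return np.count_nonzero(a & b) / union
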