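"""Landmark-based similarity registration between angiography modalities.

The two modalities (en face choriocapillaris OCTA and ICGA) are aligned
by an orientation-preserving similarity transform — translation, rotation
and isotropic rescaling — estimated from user-specified landmark pairs.
Convention: ICGA is the *moving* (source) image and OCTA the *fixed*
(target) image, so all agreement computation happens in the OCTA frame,
whose scan defines the 6 x 6 mm analysis window.  Pixel coordinates have
the origin at the top-left, x rightward, y downward; conversion to mm
happens after registration.

Estimation uses the closed-form least-squares (Umeyama/Procrustes) fit
with the determinant constrained positive, as provided by
``skimage.transform.SimilarityTransform``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import SimilarityTransform as _SkSimilarity

from .errors import DegenerateConfigurationError, EmptyInputError, InsufficientLandmarksError
from .geometry import Circle, Point2D, Polygon2D

__all__ = [
    "LandmarkPair",
    "SimilarityTransform",
    "estimate_similarity",
    "apply_transform",
    "registration_residual",
]


@dataclass(frozen=True)
class LandmarkPair:
    """One corresponding landmark: source (moving) and target (fixed) pixels."""

    source: Point2D
    target: Point2D


@dataclass(frozen=True)
class SimilarityTransform:
    """scale * R(rotation) @ p + translation, orientation-preserving (scale > 0)."""

    scale: float
    rotation: float  # radians, counter-clockwise in the x-right/y-down frame
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix mapping source to target coordinates."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        tx, ty = self.translation
        return np.array(
            [
                [self.scale * c, -self.scale * s, tx],
                [self.scale * s, self.scale * c, ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx, ty = self.translation
        return SimilarityTransform(
            scale=inv_scale,
            rotation=-self.rotation,
            translation=(
                -inv_scale * (c * tx - s * ty),
                -inv_scale * (s * tx + c * ty),
            ),
        )

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        m = self.matrix
        return pts @ m[:2, :2].T + m[:2, 2]

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(scale=1.0, rotation=0.0, translation=(0.0, 0.0))


def estimate_similarity(pairs: list[LandmarkPair]) -> SimilarityTransform:
    """Least-squares similarity transform from landmark correspondences.

    Minimises the sum of squared target-space residuals over scale,
    rotation and translation, with reflections excluded.  Two
    non-coincident pairs determine the transform exactly; three (the
    clinical protocol) give an over-determined fit.

    Raises
    ------
    InsufficientLandmarksError
        with fewer than 2 pairs.
    DegenerateConfigurationError
        when all source points coincide.
    """
    if len(pairs) < 2:
        raise InsufficientLandmarksError(
            f"similarity estimation needs >=2 landmark pairs, got {len(pairs)}"
        )
    src = np.array([[p.source.x, p.source.y] for p in pairs])
    dst = np.array([[p.target.x, p.target.y] for p in pairs])
    if np.allclose(src, src[0], atol=1e-12):
        raise DegenerateConfigurationError("all source landmarks coincide")
    if hasattr(_SkSimilarity, "from_estimate"):
        tf = _SkSimilarity.from_estimate(src, dst)
        ok = bool(tf)
    else:  # older scikit-image
        tf = _SkSimilarity()
        ok = tf.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tf.params)):
        raise DegenerateConfigurationError("landmark configuration is degenerate")
    return SimilarityTransform(
        scale=float(tf.scale),
        rotation=float(tf.rotation),
        translation=(float(tf.translation[0]), float(tf.translation[1])),
    )


def apply_transform(t: SimilarityTransform, geometry):
    """Map a Point2D, Polygon2D or Circle through a similarity transform.

    A circle maps to a circle with its radius multiplied by ``t.scale``;
    polygon areas scale exactly by ``t.scale**2``.
    """
    if isinstance(geometry, Point2D):
        out = t.transform_points(geometry.as_array())
        return Point2D(float(out[0, 0]), float(out[0, 1]))
    if isinstance(geometry, Polygon2D):
        return Polygon2D(t.transform_points(geometry.vertices))
    if isinstance(geometry, Circle):
        c = apply_transform(t, geometry.center)
        return Circle(c, geometry.radius * t.scale)
    raise TypeError(f"cannot transform object of type {type(geometry).__name__}")


def registration_residual(t: SimilarityTransform, pairs: list[LandmarkPair]) -> float:
    """Root-mean-square distance |t(source) - target| over landmark pairs."""
    if len(pairs) == 0:
        raise EmptyInputError("registration residual of an empty pair list")
    src = np.array([[p.source.x, p.source.y] for p in pairs])
    dst = np.array([[p.target.x, p.target.y] for p in pairs])
    res = t.transform_points(src) - dst
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))


def check_landmark_count(pairs: list[LandmarkPair]) -> None:
    """Warn when fewer than the standard three landmarks are supplied."""
    if len(pairs) < 3:
        warnings.warn(
            f"only {len(pairs)} landmark pairs supplied; the standard protocol "
            "uses three non-collinear landmarks",
            stacklevel=2,
        )
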