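"""Synthetic paired OCTA/ICGA eyes with known ground truth.

The generator emulates the three choriocapillaris flow phenotypes seen
in central serous chorioretinopathy so the whole analysis pipeline can
be exercised without clinical data:

* **type A** — a coarse granulated hyper-reflective elliptical patch
  (dilated, hyper-perfused choriocapillaris);
* **type B** — a roundish dark halo around the patch, the shadow cast
  by a sufficiently thick subretinal-fluid (SRF) pocket; its presence
  is gated on a simulated SRF thickness crossing a threshold;
* **type C** — small coarse granulated hypo-reflective spots inside the
  patch (focal hypoperfusion).

The matched ICGA frame carries a mid-phase hyperfluorescent region
co-located with type A (slightly smaller and offset, as the dye image
typically is) and early-phase hypofluorescent spots co-located with
type C, all rendered through the *inverse* of a known similarity
transform, so registration can be tested against exact landmarks.

Lesions are ellipses, annuli and disks rather than realistic
choriocapillaris texture: the pipeline under test is geometric, and
simple shapes keep the circle-based Jaccard index analytically
available (the minimum enclosing circle of an axis-sampled ellipse is
the circle on its major axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure

from .errors import ConfigError, DegenerateAnnotationError
from .geometry import Circle, Point2D, Polygon2D, circle_jaccard
from .io_annotations import Annotation, EyeRecord
from .registration import LandmarkPair, SimilarityTransform, apply_transform

__all__ = [
    "TypeAConfig",
    "TypeBConfig",
    "TypeCConfig",
    "SyntheticEyeConfig",
    "SyntheticEyeTruth",
    "generate_eye",
    "simulate_grader",
    "annotate_eye",
    "generate_cohort",
    "reference_segmenter",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20190416

_ELLIPSE_VERTICES = 64
_SPOT_VERTICES = 32
#: fractional radius of the early-phase hypofluorescent spot relative to
#: its OCTA type C counterpart (the dye image under-calls hypoperfusion)
_HYPO_RADIUS_FACTOR = 0.67


@dataclass(frozen=True)
class TypeAConfig:
    """Hyper-reflective patch: ellipse center/semi-axes (mm) + texture."""

    center_mm: tuple[float, float] = (3.0, 3.0)
    semi_axes_mm: tuple[float, float] = (2.2, 1.8)  # ~12.4 mm² patch
    intensity_lift: float = 80.0
    granular_noise_sigma: float = 18.0


@dataclass(frozen=True)
class TypeBConfig:
    """Dark halo: annulus width and darkening, gated on SRF thickness (µm)."""

    halo_width_mm: float = 0.5
    darkening: float = 0.45
    srf_thickness_um: float = 538.0
    srf_threshold_um: float = 300.0


@dataclass(frozen=True)
class TypeCConfig:
    """Hypo-reflective spots inside the patch."""

    n_spots: int = 3
    radius_range_mm: tuple[float, float] = (0.10, 0.20)
    darkening: float = 0.30


@dataclass(frozen=True)
class SyntheticEyeConfig:
    """Full recipe for one synthetic eye; identical config+seed reproduce
    byte-identical outputs."""

    eye_id: str = "eye-000"
    image_size: int = 512
    field_of_view: float = 6.0  # mm, square scan window
    type_a: TypeAConfig = field(default_factory=TypeAConfig)
    type_b: TypeBConfig = field(default_factory=TypeBConfig)
    type_c: TypeCConfig = field(default_factory=TypeCConfig)
    #: maps ICGA pixel coordinates into the OCTA pixel frame
    modality_transform: SimilarityTransform = field(
        default_factory=lambda: SimilarityTransform(
            scale=1.05, rotation=math.radians(3.0), translation=(8.0, -5.0)
        )
    )
    #: linear scale of the ICGA hyperfluorescent region relative to type A
    #: (area ratio ~0.94: the flow image reads slightly larger than the dye)
    icga_hyper_scale: float = 0.968
    #: mm offset of the ICGA hyper region center in the OCTA frame
    icga_hyper_offset_mm: tuple[float, float] = (0.30, 0.0)
    grader_noise_sigma: float = 0.05  # mm
    background: float = 90.0
    background_noise_sigma: float = 6.0
    has_type_a: bool = True
    has_type_c: bool = True
    seed: int = DEFAULT_SEED

    @property
    def pixel_size(self) -> float:
        return self.field_of_view / self.image_size

    @property
    def has_type_b(self) -> bool:
        """The halo appears when the patch exists and the SRF pocket is
        thicker than the shadow threshold."""
        return (
            self.has_type_a
            and self.type_b.srf_thickness_um > self.type_b.srf_threshold_um
        )

    def validate(self) -> None:
        cx, cy = self.type_a.center_mm
        a, b = self.type_a.semi_axes_mm
        margin = max(a, b) + self.type_b.halo_width_mm
        fov = self.field_of_view
        if not (margin <= cx <= fov - margin and margin <= cy <= fov - margin):
            raise ConfigError(
                f"lesion (center {self.type_a.center_mm}, reach {margin:.2f} mm) "
                f"does not fit inside the {fov} x {fov} mm field of view"
            )
        if self.type_c.n_spots < 0 or self.type_c.radius_range_mm[0] <= 0:
            raise ConfigError("invalid type C spot configuration")


@dataclass
class SyntheticEyeTruth:
    """Ground truth for one synthetic eye."""

    config: SyntheticEyeConfig
    octa_image: np.ndarray | None
    icga_image: np.ndarray | None
    #: label -> list of pixel-coordinate polygons, per modality
    octa_polygons: dict[str, list[Polygon2D]]
    icga_polygons: dict[str, list[Polygon2D]]
    true_transform: SimilarityTransform  # ICGA px -> OCTA px
    landmarks: list[LandmarkPair]  # exact, consistent with true_transform
    analytic_ji: float | None  # circle-JI of true type A vs true ICGA hyper
    srf_thickness_um: float

    @property
    def pixel_size(self) -> float:
        return self.config.pixel_size


def _ellipse_polygon_mm(
    center: tuple[float, float], semi_axes: tuple[float, float],
    n: int = _ELLIPSE_VERTICES,
) -> np.ndarray:
    theta = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + semi_axes[0] * np.cos(theta),
         center[1] + semi_axes[1] * np.sin(theta)]
    )


def _disk_polygon_mm(center: np.ndarray, radius: float, n: int = _SPOT_VERTICES):
    theta = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def _inside_ellipse(x, y, center, semi_axes):
    return ((x - center[0]) / semi_axes[0]) ** 2 + (
        (y - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def _landmark_positions(image_size: int) -> np.ndarray:
    # three fixed, non-collinear, lesion-independent positions (OCTA px)
    return np.array(
        [[0.20, 0.25], [0.80, 0.30], [0.45, 0.80]], dtype=float
    ) * image_size


def generate_eye(
    config: SyntheticEyeConfig, render_images: bool = True
) -> SyntheticEyeTruth:
    """Generate one synthetic eye: rasters, truth polygons, exact landmarks.

    Set ``render_images=False`` to skip raster synthesis when only the
    geometric truth is needed (e.g. large simulated cohorts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size
    size = config.image_size
    t = config.modality_transform
    t_inv = t.inverse()

    ca = config.type_a.center_mm
    ax = config.type_a.semi_axes_mm

    # --- spot geometry (drawn even when type A absent: type C can occur alone)
    spots: list[tuple[np.ndarray, float]] = []
    if config.has_type_c:
        lo, hi = config.type_c.radius_range_mm
        for _ in range(config.type_c.n_spots):
            # uniform position inside the 0.6-scaled patch ellipse
            u = rng.uniform()
            phi = rng.uniform(0.0, 2 * math.pi)
            r_frac = 0.6 * math.sqrt(u)
            center = np.array(
                [ca[0] + r_frac * ax[0] * math.cos(phi),
                 ca[1] + r_frac * ax[1] * math.sin(phi)]
            )
            spots.append((center, float(rng.uniform(lo, hi))))

    # --- truth polygons, OCTA frame (pixels)
    octa_polys: dict[str, list[Polygon2D]] = {"A": [], "B": [], "C": []}
    icga_polys: dict[str, list[Polygon2D]] = {"hyper": [], "hypo": []}

    hyper_center = (
        ca[0] + config.icga_hyper_offset_mm[0],
        ca[1] + config.icga_hyper_offset_mm[1],
    )
    hyper_axes = (
        ax[0] * config.icga_hyper_scale,
        ax[1] * config.icga_hyper_scale,
    )

    analytic_ji = None
    if config.has_type_a:
        octa_polys["A"].append(Polygon2D(_ellipse_polygon_mm(ca, ax) / px))
        if config.has_type_b:
            w = config.type_b.halo_width_mm
            outer = (ax[0] + w, ax[1] + w)
            octa_polys["B"].append(Polygon2D(_ellipse_polygon_mm(ca, outer) / px))
        hyper_octa_px = _ellipse_polygon_mm(hyper_center, hyper_axes) / px
        icga_polys["hyper"].append(
            Polygon2D(t_inv.transform_points(hyper_octa_px))
        )
        # circumcircles of the true regions in the OCTA mm frame:
        # for an axis-sampled ellipse the minimum enclosing circle sits on
        # the major axis, so both are known in closed form
        circ_a = Circle(Point2D(*ca), max(ax))
        circ_h = Circle(Point2D(*hyper_center), max(hyper_axes))
        analytic_ji = circle_jaccard(circ_a, circ_h)

    for center, radius in spots:
        octa_polys["C"].append(Polygon2D(_disk_polygon_mm(center, radius) / px))
        hypo_octa_px = _disk_polygon_mm(center, radius * _HYPO_RADIUS_FACTOR) / px
        icga_polys["hypo"].append(Polygon2D(t_inv.transform_points(hypo_octa_px)))

    # --- exact landmarks
    targets = _landmark_positions(size)
    sources = t_inv.transform_points(targets)
    landmarks = [
        LandmarkPair(source=Point2D(*s), target=Point2D(*tt))
        for s, tt in zip(sources, targets)
    ]

    octa_img = icga_img = None
    if render_images:
        octa_img = _render_octa(config, spots, rng)
        icga_img = _render_icga(config, hyper_center, hyper_axes, spots, rng)

    return SyntheticEyeTruth(
        config=config,
        octa_image=octa_img,
        icga_image=icga_img,
        octa_polygons=octa_polys,
        icga_polygons=icga_polys,
        true_transform=t,
        landmarks=landmarks,
        analytic_ji=analytic_ji,
        srf_thickness_um=config.type_b.srf_thickness_um,
    )


def _pixel_grid_mm(size: int, px: float):
    coords = (np.arange(size) + 0.5) * px
    return np.meshgrid(coords, coords)  # x (cols), y (rows)


def _render_octa(config, spots, rng) -> np.ndarray:
    size, px = config.image_size, config.pixel_size
    x, y = _pixel_grid_mm(size, px)
    img = np.full((size, size), config.background, dtype=float)
    if config.background_noise_sigma > 0:
        img += rng.normal(0.0, config.background_noise_sigma, img.shape)
    ca, ax = config.type_a.center_mm, config.type_a.semi_axes_mm
    if config.has_type_a:
        inside = _inside_ellipse(x, y, ca, ax)
        lift = np.full(img.shape, config.type_a.intensity_lift)
        if config.type_a.granular_noise_sigma > 0:
            lift += rng.normal(0.0, config.type_a.granular_noise_sigma, img.shape)
        img[inside] += lift[inside]
        if config.has_type_b:
            w = config.type_b.halo_width_mm
            halo = _inside_ellipse(x, y, ca, (ax[0] + w, ax[1] + w)) & ~inside
            img[halo] *= config.type_b.darkening
    for center, radius in spots:
        spot = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2
        img[spot] *= config.type_c.darkening
    return np.clip(img, 0, 255).astype(np.uint8)


def _render_icga(config, hyper_center, hyper_axes, spots, rng) -> np.ndarray:
    size = config.image_size
    px = config.pixel_size
    # evaluate geometry in the OCTA mm frame at every ICGA pixel center
    cols, rows = np.meshgrid(np.arange(size) + 0.5, np.arange(size) + 0.5)
    icga_px = np.column_stack([cols.ravel(), rows.ravel()])
    octa_mm = config.modality_transform.transform_points(icga_px) * px
    x = octa_mm[:, 0].reshape(size, size)
    y = octa_mm[:, 1].reshape(size, size)
    img = np.full((size, size), 100.0)
    if config.background_noise_sigma > 0:
        img += rng.normal(0.0, config.background_noise_sigma, img.shape)
    if config.has_type_a:
        img[_inside_ellipse(x, y, hyper_center, hyper_axes)] += 70.0
    for center, radius in spots:
        r_hypo = radius * _HYPO_RADIUS_FACTOR
        spot = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= r_hypo**2
        img[spot] -= 60.0
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# grader simulation
# ---------------------------------------------------------------------------


def simulate_grader(
    truth_polygon: Polygon2D,
    noise_sigma: float,
    seed: int,
    pixel_size: float = 1.0,
    max_retries: int = 20,
) -> Polygon2D:
    """Perturb a truth polygon the way a human grader's outline varies.

    Each vertex moves radially (along the ray from the polygon centroid)
    by a zero-mean Gaussian of standard deviation ``noise_sigma`` (mm;
    ``pixel_size`` converts to the polygon's pixel units).  The draw is
    retried until the perturbed polygon is simple; ``noise_sigma = 0``
    returns an exact copy.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return Polygon2D(truth_polygon.vertices.copy())
    rng = np.random.default_rng(seed)
    v = truth_polygon.vertices
    centroid = v.mean(axis=0)
    radial = v - centroid
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = radial / norms
    sigma_px = noise_sigma / pixel_size
    for _ in range(max_retries):
        disp = rng.normal(0.0, sigma_px, size=(len(v), 1))
        # clip so no vertex crosses the centroid (keeps the outline star-shaped)
        disp = np.maximum(disp, -0.9 * norms)
        cand = Polygon2D(v + unit * disp)
        if cand.is_simple():
            return cand
    raise DegenerateAnnotationError(
        f"could not produce a simple polygon after {max_retries} draws "
        f"(sigma {noise_sigma} mm)"
    )


def annotate_eye(
    truth: SyntheticEyeTruth,
    grader: str,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> list[Annotation]:
    """Simulated annotations by one grader for every truth region."""
    cfg = truth.config
    sigma = cfg.grader_noise_sigma if noise_sigma is None else noise_sigma
    base_seed = cfg.seed if seed is None else seed
    px = cfg.pixel_size
    out: list[Annotation] = []
    counter = 0
    modality_of = {"A": "OCTA", "B": "OCTA", "C": "OCTA",
                   "hyper": "ICGA_mid", "hypo": "ICGA_early"}
    for polys, labels in ((truth.octa_polygons, ("A", "B", "C")),
                          (truth.icga_polygons, ("hyper", "hypo"))):
        for label in labels:
            for poly in polys.get(label, []):
                counter += 1
                noisy = simulate_grader(
                    poly, sigma, seed=(base_seed + 7919 * counter) % (2**31),
                    pixel_size=px,
                )
                out.append(
                    Annotation(
                        eye_id=cfg.eye_id, modality=modality_of[label],
                        grader=grader, label=label, polygon=noisy,
                        pixel_size=px,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: default per-eye prevalences and SRF-thickness (µm) distributions; the
#: dark-halo sign is *derived* from the SRF gate, acute eyes drawing from
#: the thicker distribution, so it comes out more frequent in acute disease
DEFAULT_PREVALENCE_PARAMS = {
    "type_a": 61 / 66,
    "type_c": 1.0,
    "srf_acute_mean": 500.0,
    "srf_acute_sd": 200.0,
    "srf_chronic_mean": 310.0,
    "srf_chronic_sd": 150.0,
    "area_type_a_mean": 12.7,
    "area_type_a_sd": 3.8,
    "icga_area_ratio_mean": 0.937,
    "icga_area_ratio_sd": 0.10,
}


def generate_cohort(
    n_eyes: int,
    acute_fraction: float = 42 / 66,
    prevalence_params: dict | None = None,
    seed: int = DEFAULT_SEED,
    render_images: bool = False,
) -> tuple[list[SyntheticEyeTruth], list[EyeRecord]]:
    """Generate a cohort of synthetic eyes plus matching clinical records.

    The acute/chronic split is deterministic (``round(n * acute_fraction)``
    acute eyes); lesion presence is drawn per configured prevalences, and
    the dark-halo (type B) sign follows from each eye's simulated SRF
    thickness crossing the shadow threshold — acute eyes draw thicker SRF,
    so the halo is more frequent in acute disease.
    """
    if n_eyes < 1:
        raise ConfigError("n_eyes must be >= 1")
    if not 0.0 <= acute_fraction <= 1.0:
        raise ConfigError("acute_fraction must be in [0, 1]")
    params = dict(DEFAULT_PREVALENCE_PARAMS)
    if prevalence_params:
        params.update(prevalence_params)
    for k in ("type_a", "type_c"):
        if not 0.0 <= params[k] <= 1.0:
            raise ConfigError(f"prevalence {k} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_acute = int(round(n_eyes * acute_fraction))

    truths: list[SyntheticEyeTruth] = []
    records: list[EyeRecord] = []
    for i in range(n_eyes):
        duration = "acute" if i < n_acute else "chronic"
        has_a = bool(rng.uniform() < params["type_a"])
        has_c = bool(rng.uniform() < params["type_c"])
        if duration == "acute":
            srf = max(0.0, rng.normal(params["srf_acute_mean"],
                                      params["srf_acute_sd"]))
        else:
            srf = max(0.0, rng.normal(params["srf_chronic_mean"],
                                      params["srf_chronic_sd"]))

        area_a = float(np.clip(
            rng.normal(params["area_type_a_mean"], params["area_type_a_sd"]),
            4.0, 16.0))
        ratio = float(np.clip(
            rng.normal(params["icga_area_ratio_mean"],
                       params["icga_area_ratio_sd"]), 0.5, 1.4))
        # ellipse semi-axes realising the drawn area with a mild aspect
        # ratio; the semi-major axis is capped so lesion + halo stay
        # inside the 6 mm window (the aspect flattens, the area is kept)
        aspect = float(rng.uniform(1.05, 1.3))
        b_axis = math.sqrt(area_a / (math.pi * aspect))
        a_axis = aspect * b_axis
        jitter = 0.08
        a_limit = 3.0 - TypeBConfig().halo_width_mm - jitter - 0.02
        if a_axis > a_limit:
            a_axis = a_limit
            b_axis = area_a / (math.pi * a_axis)

        cfg = SyntheticEyeConfig(
            eye_id=f"eye-{i:03d}",
            type_a=TypeAConfig(
                center_mm=(
                    3.0 + float(rng.uniform(-jitter, jitter)),
                    3.0 + float(rng.uniform(-jitter, jitter)),
                ),
                semi_axes_mm=(a_axis, b_axis),
            ),
            type_b=TypeBConfig(srf_thickness_um=srf),
            type_c=TypeCConfig(n_spots=int(rng.integers(1, 5))),
            modality_transform=SimilarityTransform(
                scale=float(rng.uniform(0.95, 1.10)),
                rotation=float(rng.uniform(-math.radians(5), math.radians(5))),
                translation=(float(rng.uniform(-10, 10)),
                             float(rng.uniform(-10, 10))),
            ),
            icga_hyper_scale=math.sqrt(ratio),
            has_type_a=has_a,
            has_type_c=has_c,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = generate_eye(cfg, render_images=render_images)
        truths.append(truth)

        area_a_true = math.pi * a_axis * b_axis if has_a else None
        records.append(
            EyeRecord(
                eye_id=cfg.eye_id,
                duration_class=duration,
                has_type_a=has_a,
                has_type_b=cfg.has_type_b,
                has_type_c=has_c,
                area_type_a=area_a_true,
                area_hyper_icga=(area_a_true * ratio if has_a else None),
                area_type_c=(
                    sum(math.pi * r * r
                        for _, r in _spot_list(truth)) if has_c else None
                ),
                area_hypo_icga=(
                    sum(math.pi * (r * _HYPO_RADIUS_FACTOR) ** 2
                        for _, r in _spot_list(truth)) if has_c else None
                ),
                srf_thickness=srf,
            )
        )
    return truths, records


def _spot_list(truth: SyntheticEyeTruth) -> list[tuple[np.ndarray, float]]:
    out = []
    px = truth.pixel_size
    for poly in truth.octa_polygons.get("C", []):
        v = poly.vertices * px
        center = v.mean(axis=0)
        out.append((center, float(np.linalg.norm(v[0] - center))))
    return out


# ---------------------------------------------------------------------------
# reference threshold segmenter (plumbing only; grading is manual in practice)
# ---------------------------------------------------------------------------


def _contour_polygons(mask: np.ndarray, min_vertices: int = 8) -> list[Polygon2D]:
    polys = []
    padded = np.pad(mask.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        if len(contour) < min_vertices:
            continue
        # (row, col) -> (x, y), undo padding
        xy = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
        if len(xy) > 120:  # decimate long raster contours
            xy = xy[:: len(xy) // 120 + 1]
        if len(xy) >= 3:
            try:
                p = Polygon2D(xy)
            except Exception:
                continue
            if p.is_simple():
                polys.append(p)
    return polys


def reference_segmenter(
    image: np.ndarray,
    bright_threshold: float,
    dark_threshold: float,
    min_area_mm2: float,
    pixel_size: float,
) -> dict[str, list[Polygon2D]]:
    """Threshold-based candidate regions for the three lesion labels.

    A simple stand-in for manual grading so the pipeline runs end to end
    on synthetic images: connected bright components become type A
    candidates; dark components inside a type A candidate become type C;
    dark components adjacent to (but outside) a type A candidate become
    type B.  Components smaller than ``min_area_mm2`` are dropped.
    Returns ``{"A": [...], "B": [...], "C": [...]}`` pixel polygons.
    """
    img = np.asarray(image, dtype=float)
    min_px = min_area_mm2 / pixel_size**2

    bright = binary_fill_holes(img > bright_threshold)
    labels_b = measure.label(bright)
    a_polys: list[Polygon2D] = []
    for region in measure.regionprops(labels_b):
        if region.area < min_px:
            continue
        a_polys.extend(_contour_polygons(labels_b == region.label))

    a_shapes = [p.to_shapely() for p in a_polys]
    dark = img < dark_threshold
    labels_d = measure.label(dark)
    c_polys: list[Polygon2D] = []
    b_polys: list[Polygon2D] = []
    halo_reach_px = 0.7 / pixel_size  # adjacency band for the halo (mm)
    for region in measure.regionprops(labels_d):
        if region.area < min_px:
            continue
        region_mask = labels_d == region.label
        polys = _contour_polygons(region_mask)
        if not polys:
            continue
        # one polygon per component: the outer contour encloses the rest
        polys = [max(polys, key=lambda p: p.to_shapely().area)]
        # spots sit (mostly) inside the filled bright patch; the halo is
        # an annulus adjacent to, but outside, the patch
        frac_inside = np.count_nonzero(region_mask & bright) / region.area
        if frac_inside >= 0.5:
            c_polys.extend(polys)
        elif a_shapes and any(
            s.distance(p.to_shapely()) <= halo_reach_px
            for s in a_shapes for p in polys
        ):
            b_polys.extend(polys)
    return {"A": a_polys, "B": b_polys, "C": c_polys}
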