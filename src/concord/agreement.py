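"""Per-eye and per-cohort agreement analysis.

The pipeline mirrors how multimodal lesion annotations are compared in
clinical reading-centre practice:

1. per grader/modality/label, confluent (overlapping or near-touching)
   annotated areas are amalgamated into single regions;
2. agreement between two annotations is the Jaccard index of their
   *circumcircles* (smallest enclosing circles), not of the raw borders —
   borders of diffuse choriocapillaris lesions are hard to reproduce,
   and the circular treatment spot used in photodynamic therapy makes
   the circumcircle the clinically meaningful unit;
3. cross-modality comparison maps the ICGA region through the estimated
   similarity transform into the OCTA frame before measuring overlap;
4. matched areas are classified equal / larger / smaller with a relative
   tolerance band (default 10% of the ICGA reference area);
5. cohort summaries report lesion-type prevalences, area-relation
   counts, acute-vs-chronic cross-tabulations (chi-squared) and a paired
   t-test on the matched OCTA vs ICGA areas.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from shapely.ops import unary_union

from .errors import (
    DegenerateTableError,
    EmptyAnnotationError,
    InconsistentGroupError,
    InsufficientDataError,
    UndefinedReferenceAreaError,
)
from .geometry import Circle, Polygon2D, circle_jaccard, min_enclosing_circle
from .io_annotations import Annotation, EyeRecord
from .registration import SimilarityTransform, apply_transform

logger = logging.getLogger(__name__)

__all__ = [
    "MergedRegion",
    "AgreementResult",
    "CohortSummary",
    "merge_confluent",
    "interobserver_jaccard",
    "cross_modality_jaccard",
    "classify_area_relation",
    "area_weighted_mean_ji",
    "paired_t_test",
    "two_by_two_chisq",
    "cohort_summary",
    "round_half_up",
    "read_agreements",
    "write_agreements",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MergedRegion:
    """One amalgamated abnormal area: one or more polygons, shared metadata."""

    eye_id: str
    modality: str
    grader: str
    label: str
    polygons: tuple[Polygon2D, ...]  # pixel coordinates
    pixel_size: float  # mm / pixel

    def vertices_mm(self) -> np.ndarray:
        """All member-polygon vertices in physical (mm) coordinates."""
        return np.vstack([p.vertices for p in self.polygons]) * self.pixel_size

    def area_mm2(self) -> float:
        """Area of the union of the member polygons, mm²."""
        union = unary_union([p.to_shapely() for p in self.polygons])
        return union.area * self.pixel_size**2

    def circumcircle_mm(self) -> Circle:
        """Minimum enclosing circle of the region, in mm."""
        return min_enclosing_circle(self.vertices_mm())


@dataclass
class AgreementResult:
    """A single Jaccard comparison plus the two region areas (mm²)."""

    eye_id: str
    comparison: str  # interobserver_octa | interobserver_icga | octa_vs_icga
    jaccard: float
    area_first: float
    area_second: float
    relation: str | None = None  # equal | larger | smaller (octa_vs_icga only)


# ---------------------------------------------------------------------------
# amalgamation
# ---------------------------------------------------------------------------


def merge_confluent(
    annotations: list[Annotation], gap_tolerance: float = 0.0
) -> list[MergedRegion]:
    """Amalgamate confluent annotated areas into single regions.

    Annotations whose polygons overlap, touch, or lie within
    ``gap_tolerance`` (mm) of each other are merged, transitively: a
    chain of pairwise-close polygons becomes one region.  All inputs
    must share eye, modality, grader and label.
    """
    if not annotations:
        return []
    key = (annotations[0].eye_id, annotations[0].modality,
           annotations[0].grader, annotations[0].label)
    for a in annotations[1:]:
        if (a.eye_id, a.modality, a.grader, a.label) != key:
            raise InconsistentGroupError(
                "merge_confluent requires annotations sharing eye/modality/"
                f"grader/label; got {key} and "
                f"{(a.eye_id, a.modality, a.grader, a.label)}"
            )
    px = annotations[0].pixel_size
    shapes = [a.polygon.to_shapely() for a in annotations]
    n = len(shapes)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if shapes[i].distance(shapes[j]) * px <= gap_tolerance:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    regions = [
        MergedRegion(
            eye_id=key[0], modality=key[1], grader=key[2], label=key[3],
            polygons=tuple(annotations[i].polygon for i in idx),
            pixel_size=px,
        )
        for idx in groups.values()
    ]
    # stable output order: by first member's appearance in the input
    regions.sort(key=lambda r: annotations.index(
        next(a for a in annotations if a.polygon is r.polygons[0])))
    return regions


# ---------------------------------------------------------------------------
# Jaccard comparisons
# ---------------------------------------------------------------------------


def interobserver_jaccard(
    region_grader1: MergedRegion, region_grader2: MergedRegion
) -> AgreementResult:
    """Circumcircle Jaccard index between two graders' regions (same modality)."""
    for r in (region_grader1, region_grader2):
        if not r.polygons:
            raise EmptyAnnotationError(f"empty region for grader {r.grader}")
    if (region_grader1.eye_id != region_grader2.eye_id
            or region_grader1.modality != region_grader2.modality
            or region_grader1.label != region_grader2.label):
        raise InconsistentGroupError(
            "interobserver comparison requires matching eye, modality and label"
        )
    ji = circle_jaccard(
        region_grader1.circumcircle_mm(), region_grader2.circumcircle_mm()
    )
    comparison = (
        "interobserver_octa"
        if region_grader1.modality == "OCTA"
        else "interobserver_icga"
    )
    result = AgreementResult(
        eye_id=region_grader1.eye_id,
        comparison=comparison,
        jaccard=ji,
        area_first=region_grader1.area_mm2(),
        area_second=region_grader2.area_mm2(),
    )
    logger.info(
        "eye %s %s: JI=%.4f areas=(%.3f, %.3f) mm^2",
        result.eye_id, comparison, ji, result.area_first, result.area_second,
    )
    return result


def cross_modality_jaccard(
    octa_region: MergedRegion,
    icga_region: MergedRegion,
    t: SimilarityTransform,
    field_of_view_mm: float | None = None,
    area_tolerance: float = 0.10,
) -> AgreementResult:
    """Circumcircle Jaccard of an OCTA region vs an ICGA region.

    ``t`` maps ICGA pixel coordinates into the OCTA pixel frame (the
    fixed frame where the scan window lives); both regions are then
    converted to mm with the OCTA pixel size and compared.  The result
    carries both areas and the equal/larger/smaller classification of
    the OCTA area against the ICGA reference.

    When ``field_of_view_mm`` is given and the mapped ICGA region falls
    entirely outside the scan window, an out-of-field warning is issued
    (the JI is still computed).
    """
    if not octa_region.polygons or not icga_region.polygons:
        raise EmptyAnnotationError("cross-modality comparison of an empty region")
    px = octa_region.pixel_size
    mapped = [apply_transform(t, p) for p in icga_region.polygons]
    mapped_mm = np.vstack([p.vertices for p in mapped]) * px
    if field_of_view_mm is not None:
        inside = (
            (mapped_mm[:, 0] >= 0) & (mapped_mm[:, 0] <= field_of_view_mm)
            & (mapped_mm[:, 1] >= 0) & (mapped_mm[:, 1] <= field_of_view_mm)
        )
        if not inside.any():
            warnings.warn(
                f"eye {octa_region.eye_id}: mapped ICGA region lies entirely "
                "outside the OCTA field of view",
                stacklevel=2,
            )
    circ_octa = octa_region.circumcircle_mm()
    circ_icga = min_enclosing_circle(mapped_mm)
    ji = circle_jaccard(circ_octa, circ_icga)
    area_octa = octa_region.area_mm2()
    area_icga = unary_union([p.to_shapely() for p in mapped]).area * px**2
    relation = (
        classify_area_relation(area_octa, area_icga, tolerance=area_tolerance)
        if area_icga > 0
        else None
    )
    result = AgreementResult(
        eye_id=octa_region.eye_id,
        comparison="octa_vs_icga",
        jaccard=ji,
        area_first=area_octa,
        area_second=area_icga,
        relation=relation,
    )
    logger.info(
        "eye %s octa_vs_icga: JI=%.4f areas=(%.3f, %.3f) mm^2 relation=%s",
        result.eye_id, ji, area_octa, area_icga, relation,
    )
    return result


def classify_area_relation(
    area_octa: float, area_icga: float, tolerance: float = 0.10
) -> str:
    """Classify the OCTA area against the ICGA reference area.

    ``equal`` when the absolute difference is within ``tolerance`` (a
    fraction, default 10%) of the ICGA area, else ``larger``/``smaller``
    by the sign of the difference.  The boundary counts as equal.
    """
    if area_icga <= 0:
        raise UndefinedReferenceAreaError("ICGA reference area must be positive")
    if area_octa < 0:
        raise ValueError("areas must be non-negative")
    diff = area_octa - area_icga
    if abs(diff) <= tolerance * area_icga:
        return "equal"
    return "larger" if diff > 0 else "smaller"


def area_weighted_mean_ji(results: list[AgreementResult]) -> float:
    """Area-weighted mean JI over regions (one eye with several lesions).

    Weights are the union areas (first + second) of each comparison, so
    large lesions dominate the per-eye figure.
    """
    if not results:
        raise InsufficientDataError("no agreement results to average")
    w = np.array([r.area_first + r.area_second for r in results])
    j = np.array([r.jaccard for r in results])
    if w.sum() == 0:
        return float(j.mean())
    return float(np.average(j, weights=w))


_AGREEMENT_COLS = [
    "eye_id", "comparison", "jaccard", "area_first", "area_second", "relation",
]


def write_agreements(results: list[AgreementResult], path) -> None:
    """Serialise agreement results to CSV (one row per comparison)."""
    rows = [
        {
            "eye_id": r.eye_id,
            "comparison": r.comparison,
            "jaccard": r.jaccard,
            "area_first": r.area_first,
            "area_second": r.area_second,
            "relation": "" if r.relation is None else r.relation,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_AGREEMENT_COLS).to_csv(path, index=False)


def read_agreements(path) -> list[AgreementResult]:
    df = pd.read_csv(path, dtype={"eye_id": str})
    missing = set(_AGREEMENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"agreement table missing columns {sorted(missing)}")
    return [
        AgreementResult(
            eye_id=str(row["eye_id"]),
            comparison=str(row["comparison"]),
            jaccard=float(row["jaccard"]),
            area_first=float(row["area_first"]),
            area_second=float(row["area_second"]),
            relation=None if pd.isna(row["relation"]) or row["relation"] == ""
            else str(row["relation"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def paired_t_test(x, y) -> tuple[float, float]:
    """Student's paired t-test; returns (t statistic, two-sided p).

    A degenerate case with every paired difference exactly zero returns
    ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    d = x - y
    if np.ptp(d) == 0:  # zero-variance differences
        if d[0] == 0:
            return 0.0, 1.0
        return (math.copysign(math.inf, d[0]), 0.0)
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def two_by_two_chisq(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table [[a, b], [c, d]].

    ``yates`` enables the continuity correction (off by default).  All
    margins must be positive.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers, got {v}")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("2x2 table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


def _pct(count: int, n: int) -> float:
    return round_half_up(100.0 * count / n, 1)


def _mean_sd(values: list[float]) -> tuple[float, float] | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass
class CohortSummary:
    """Cohort-level tabulation: prevalences, agreement, tests."""

    n_eyes: int
    counts: dict[str, int]
    percents: dict[str, float]  # 1-decimal, half-up, denominator n_eyes
    relation_counts: dict[str, int]
    relation_percents: dict[str, float]
    ji_stats: dict[str, tuple[float, float]]  # comparison -> (mean, sd)
    type_b_by_duration: dict[str, int] = field(default_factory=dict)
    chisq_type_b_duration: tuple[float, float] | None = None
    paired_t_areas: tuple[float, float] | None = None
    area_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


def cohort_summary(
    records: list[EyeRecord],
    agreements: list[AgreementResult] | None = None,
    yates: bool = False,
) -> CohortSummary:
    """Tabulate a cohort of eye records (plus optional agreement results).

    Computes lesion-type prevalences and combination counts with
    1-decimal half-up percents; area-relation counts; the acute/chronic
    cross-tabulation of the dark-halo (type B) sign with a chi-squared
    test; a paired t-test of matched OCTA vs ICGA areas; and mean ± SD
    of Jaccard indices per comparison type.
    """
    if not records:
        raise InsufficientDataError("cohort summary of an empty record list")
    agreements = agreements or []
    n = len(records)

    counts = {
        "type_a": sum(r.has_type_a for r in records),
        "type_b": sum(r.has_type_b for r in records),
        "type_c": sum(r.has_type_c for r in records),
        "all_three": sum(
            r.has_type_a and r.has_type_b and r.has_type_c for r in records
        ),
        "a_and_c_only": sum(
            r.has_type_a and not r.has_type_b and r.has_type_c for r in records
        ),
        "c_only": sum(
            not r.has_type_a and not r.has_type_b and r.has_type_c for r in records
        ),
    }
    percents = {k: _pct(v, n) for k, v in counts.items()}

    relation_counts = {"equal": 0, "larger": 0, "smaller": 0}
    for res in agreements:
        if res.relation is not None:
            relation_counts[res.relation] += 1
    relation_percents = {k: _pct(v, n) for k, v in relation_counts.items()}

    ji_stats = {}
    for comparison in ("interobserver_octa", "interobserver_icga", "octa_vs_icga"):
        vals = [r.jaccard for r in agreements if r.comparison == comparison]
        ms = _mean_sd(vals)
        if ms is not None:
            ji_stats[comparison] = ms

    # acute/chronic cross-tab of the type B (dark halo) sign
    tb = {
        "acute_b": sum(
            r.has_type_b and r.duration_class == "acute" for r in records
        ),
        "acute_no_b": sum(
            not r.has_type_b and r.duration_class == "acute" for r in records
        ),
        "chronic_b": sum(
            r.has_type_b and r.duration_class == "chronic" for r in records
        ),
        "chronic_no_b": sum(
            not r.has_type_b and r.duration_class == "chronic" for r in records
        ),
    }
    percents["type_b_acute"] = _pct(tb["acute_b"], n)
    percents["type_b_chronic"] = _pct(tb["chronic_b"], n)
    try:
        chisq = two_by_two_chisq(
            tb["acute_b"], tb["acute_no_b"], tb["chronic_b"], tb["chronic_no_b"],
            yates=yates,
        )
    except DegenerateTableError:
        chisq = None

    # paired t on matched areas
    matched = [
        (r.area_type_a, r.area_hyper_icga)
        for r in records
        if r.area_type_a is not None and r.area_hyper_icga is not None
    ]
    paired = None
    area_stats: dict[str, tuple[float, float]] = {}
    if len(matched) >= 2:
        octa_areas = [m[0] for m in matched]
        icga_areas = [m[1] for m in matched]
        paired = paired_t_test(octa_areas, icga_areas)
        area_stats["type_a_octa"] = _mean_sd(octa_areas)
        area_stats["hyper_icga"] = _mean_sd(icga_areas)

    return CohortSummary(
        n_eyes=n,
        counts=counts,
        percents=percents,
        relation_counts=relation_counts,
        relation_percents=relation_percents,
        ji_stats=ji_stats,
        type_b_by_duration=tb,
        chisq_type_b_duration=chisq,
        paired_t_areas=paired,
        area_stats=area_stats,
    )
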