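"""Readers and writers for images, annotations, landmarks and cohort tables.

Unit discipline enforced here and relied on everywhere else:

* polygon vertices are stored in **pixels**, with the physical pixel
  size (mm/pixel) carried alongside, so annotations stay aligned with
  their source image;
* every area leaving the package is in mm², every retinal thickness in µm;
* pixel size = field-of-view / image width (6 mm / width for a standard
  6 x 6 mm en face scan).

Annotations are a JSON list of objects
``{eye_id, modality, grader, label, pixel_size_mm, polygon: [[x, y], ...]}``
— a diff-able, language-neutral container.  An importer for ImageJ
``.roi``/``.zip`` polygon ROIs is provided as well, since lesion grading
is conventionally done in ImageJ.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import BinaryIO

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import AnnotationSchemaError
from .geometry import Polygon2D
from .registration import LandmarkPair
from .geometry import Point2D

__all__ = [
    "MODALITIES",
    "LABELS",
    "Annotation",
    "EyeRecord",
    "read_image",
    "read_annotations",
    "write_annotations",
    "read_landmarks",
    "write_landmarks",
    "read_cohort_table",
    "write_cohort_table",
    "read_imagej_roi",
]

MODALITIES = ("OCTA", "ICGA_early", "ICGA_mid")
#: closed label vocabulary: OCTA lesion types A/B/C; ICGA hyper/hypo-fluorescence
LABELS = ("A", "B", "C", "hyper", "hypo")
DURATION_CLASSES = ("acute", "chronic")


@dataclass(frozen=True)
class Annotation:
    """A labelled lesion polygon from one grader on one modality of one eye."""

    eye_id: str
    modality: str
    grader: str
    label: str
    polygon: Polygon2D  # pixel coordinates
    pixel_size: float  # mm / pixel

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise AnnotationSchemaError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.label not in LABELS:
            raise AnnotationSchemaError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        if not self.pixel_size > 0:
            raise AnnotationSchemaError(f"pixel_size must be > 0, got {self.pixel_size}")

    def polygon_mm(self) -> Polygon2D:
        """The polygon converted to physical (mm) coordinates."""
        return Polygon2D(self.polygon.vertices * self.pixel_size)


@dataclass
class EyeRecord:
    """Per-eye clinical-style record used by the cohort summaries.

    ``duration_class`` follows the conventional split: acute = symptom
    duration <= 6 months, chronic = > 6 months.  Areas are mm²,
    subretinal-fluid thickness is µm; optional fields are ``None`` when
    unmeasured.
    """

    eye_id: str
    duration_class: str
    has_type_a: bool
    has_type_b: bool
    has_type_c: bool
    area_type_a: float | None = None
    area_hyper_icga: float | None = None
    area_type_c: float | None = None
    area_hypo_icga: float | None = None
    srf_thickness: float | None = None

    def __post_init__(self) -> None:
        if self.duration_class not in DURATION_CLASSES:
            raise ValueError(
                f"duration_class must be one of {DURATION_CLASSES}, "
                f"got {self.duration_class!r}"
            )
        for f in fields(self):
            if f.name.startswith("area_"):
                v = getattr(self, f.name)
                if v is not None and v < 0:
                    raise ValueError(f"{f.name} must be non-negative, got {v}")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(path: str | Path, field_of_view_mm: float = 6.0) -> tuple[np.ndarray, float]:
    """Load an 8-bit grayscale en face image and derive its pixel size.

    Returns ``(array, pixel_size)`` with ``pixel_size = field_of_view_mm
    / width`` in mm/pixel.  PNG and TIFF are supported; colour images are
    converted to grayscale.  A non-square image paired with the (square)
    field of view triggers an aspect-mismatch warning.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse colour channels
        arr = np.asarray(Image.fromarray(arr).convert("L"))
    if arr.dtype != np.uint8:
        lo, hi = float(arr.min()), float(arr.max())
        scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr, dtype=float)
        arr = (scaled * 255).astype(np.uint8)
    h, w = arr.shape
    if h != w:
        warnings.warn(
            f"image {path.name} is {w}x{h} but the field of view is square "
            f"({field_of_view_mm} mm); pixel size derived from the width",
            stacklevel=2,
        )
    return arr, field_of_view_mm / w


# ---------------------------------------------------------------------------
# annotations (JSON)
# ---------------------------------------------------------------------------


def _annotation_to_obj(a: Annotation) -> dict:
    return {
        "eye_id": a.eye_id,
        "modality": a.modality,
        "grader": a.grader,
        "label": a.label,
        "pixel_size_mm": a.pixel_size,
        "polygon": a.polygon.vertices.tolist(),
    }


def _annotation_from_obj(obj: dict, index: int) -> Annotation:
    required = {"eye_id", "modality", "grader", "label", "pixel_size_mm", "polygon"}
    missing = required - obj.keys()
    if missing:
        raise AnnotationSchemaError(
            f"annotation record {index}: missing fields {sorted(missing)}"
        )
    poly = obj["polygon"]
    if not isinstance(poly, list) or len(poly) < 3:
        raise AnnotationSchemaError(
            f"annotation record {index}: polygon needs >=3 vertices, got {len(poly)}"
        )
    try:
        return Annotation(
            eye_id=str(obj["eye_id"]),
            modality=obj["modality"],
            grader=str(obj["grader"]),
            label=obj["label"],
            polygon=Polygon2D(np.asarray(poly, dtype=float)),
            pixel_size=float(obj["pixel_size_mm"]),
        )
    except AnnotationSchemaError as exc:
        raise AnnotationSchemaError(f"annotation record {index}: {exc}") from exc
    except Exception as exc:
        raise AnnotationSchemaError(f"annotation record {index}: {exc}") from exc


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read a JSON annotation file; every record is validated."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise AnnotationSchemaError("annotation file must contain a JSON list")
    return [_annotation_from_obj(obj, i) for i, obj in enumerate(data)]


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([_annotation_to_obj(a) for a in annotations], fh, indent=1)


# ---------------------------------------------------------------------------
# landmarks (CSV)
# ---------------------------------------------------------------------------

_LANDMARK_COLS = ["source_x", "source_y", "target_x", "target_y"]


def read_landmarks(path: str | Path) -> list[LandmarkPair]:
    """Read landmark correspondences (pixel units) from CSV."""
    df = pd.read_csv(path)
    missing = set(_LANDMARK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark file missing columns {sorted(missing)}")
    return [
        LandmarkPair(
            source=Point2D(float(r.source_x), float(r.source_y)),
            target=Point2D(float(r.target_x), float(r.target_y)),
        )
        for r in df.itertuples()
    ]


def write_landmarks(pairs: list[LandmarkPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [[p.source.x, p.source.y, p.target.x, p.target.y] for p in pairs],
        columns=_LANDMARK_COLS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort tables (CSV)
# ---------------------------------------------------------------------------

_BOOL_COLS = ["has_type_a", "has_type_b", "has_type_c"]
_OPT_COLS = [
    "area_type_a",
    "area_hyper_icga",
    "area_type_c",
    "area_hypo_icga",
    "srf_thickness",
]
_COHORT_COLS = ["eye_id", "duration_class"] + _BOOL_COLS + _OPT_COLS


def write_cohort_table(records: list[EyeRecord], path: str | Path) -> None:
    """Serialise eye records to CSV (booleans as 0/1, absent values empty)."""
    rows = []
    for r in records:
        row = {
            "eye_id": r.eye_id,
            "duration_class": r.duration_class,
        }
        for c in _BOOL_COLS:
            row[c] = int(getattr(r, c))
        for c in _OPT_COLS:
            v = getattr(r, c)
            row[c] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows, columns=_COHORT_COLS).to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> list[EyeRecord]:
    df = pd.read_csv(path, dtype={"eye_id": str})
    missing = set(_COHORT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "eye_id": str(row["eye_id"]),
            "duration_class": str(row["duration_class"]),
        }
        for c in _BOOL_COLS:
            kwargs[c] = bool(int(row[c]))
        for c in _OPT_COLS:
            v = row[c]
            kwargs[c] = None if pd.isna(v) else float(v)
        records.append(EyeRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# ImageJ ROI import
# ---------------------------------------------------------------------------

# ImageJ .roi binary layout (header is 64 bytes, big-endian):
#   0-3 magic "Iout"; 4-5 version; 6 roi type; 8-15 top/left/bottom/right;
#   16-17 n coordinates; from 64: n int16 x-offsets (from left), then
#   n int16 y-offsets (from top).
_ROI_POLYGON, _ROI_FREEHAND, _ROI_TRACED = 0, 7, 8


def _parse_roi_bytes(data: bytes, name: str) -> np.ndarray:
    if len(data) < 64 or data[:4] != b"Iout":
        raise ValueError(f"{name}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in (_ROI_POLYGON, _ROI_FREEHAND, _ROI_TRACED):
        raise ValueError(
            f"{name}: unsupported ROI type {roi_type} (only polygon/freehand)"
        )
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    (n,) = struct.unpack(">h", data[16:18])
    if n < 3:
        raise ValueError(f"{name}: ROI has {n} vertices, need >=3")
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def read_imagej_roi(path: str | Path) -> list[Polygon2D]:
    """Import polygon/freehand ROIs from an ImageJ ``.roi`` file or ``.zip`` set.

    Returns pixel-coordinate polygons; pairing with eye/grader/label
    metadata is up to the caller (ImageJ ROIs carry none).
    """
    path = Path(path)
    if path.suffix.lower() == ".zip":
        polys = []
        with zipfile.ZipFile(path) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                if info.filename.lower().endswith(".roi"):
                    polys.append(
                        Polygon2D(_parse_roi_bytes(zf.read(info), info.filename))
                    )
        return polys
    return [Polygon2D(_parse_roi_bytes(path.read_bytes(), path.name))]


def _encode_imagej_roi(vertices: np.ndarray) -> bytes:
    """Build a minimal polygon ``.roi`` blob (integer pixel vertices)."""
    v = np.asarray(vertices)
    vi = np.round(v).astype(int)
    left, top = int(vi[:, 0].min()), int(vi[:, 1].min())
    right, bottom = int(vi[:, 0].max()), int(vi[:, 1].max())
    n = len(vi)
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = _ROI_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    xs = (vi[:, 0] - left).astype(">i2").tobytes()
    ys = (vi[:, 1] - top).astype(">i2").tobytes()
    return bytes(header) + xs + ys
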