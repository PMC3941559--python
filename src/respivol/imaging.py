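"""Marker detection, metric calibration and landmark assignment.

A single lateral frame of a supine subject carries five circular adhesive
markers of known physical diameter (13 mm) placed over the manubrium
sterni (MEd), xiphoid process (AXd), inferior angle of the 10th rib (ACd),
umbilicus (COd) and right anterior superior iliac spine (EId).  This module
finds the markers in the raster, recovers the mm-per-pixel scale from the
marker diameter, and converts pixel coordinates into the physical sagittal
frame used by the volumetry stage: x runs craniocaudally in cm with its
origin under MEd, y is height above the support surface in cm (image rows
grow downward, physical y grows upward).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import (
    CalibrationError,
    DetectionError,
    GeometryError,
    ParameterError,
    SchemaError,
)

#: Craniocaudal landmark order: manubrium sterni, xiphoid process,
#: 10th-rib inferior angle, umbilicus, anterior superior iliac spine.
LANDMARKS = ("MEd", "AXd", "ACd", "COd", "EId")

#: Physical diameter of the adhesive markers, in mm.
MARKER_DIAMETER_MM = 13.0

_MIN_CIRCULARITY = 0.6
_MIN_BLOB_AREA_PX = 4


@dataclass(frozen=True)
class DetectedMarker:
    """One segmented circular blob, in pixel units."""

    center_x: float
    center_y: float
    diameter: float
    circularity: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise DetectionError("marker diameter must be positive")
        if not 0 < self.circularity <= 1:
            raise DetectionError("circularity must lie in (0, 1]")

    @property
    def score(self) -> float:
        """Ranking score: circularity times blob area."""
        return self.circularity * np.pi * (self.diameter / 2.0) ** 2


@dataclass(frozen=True)
class Calibration:
    """Metric scale recovered from the known marker diameter."""

    mm_per_px: float
    reference_diameter_mm: float = MARKER_DIAMETER_MM

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise CalibrationError("mm_per_px must be positive")

    def px_to_cm(self, px: float) -> float:
        return px * self.mm_per_px / 10.0


@dataclass(frozen=True)
class MarkerSet:
    """Calibrated landmark coordinates in the physical sagittal frame.

    ``coords`` maps each of the five landmarks to an ``(x, y)`` pair in cm.
    x increases craniocaudally from MEd; y is height above the support
    surface and must be non-negative.
    """

    coords: dict[str, tuple[float, float]]
    source: str = "detected"

    def __post_init__(self):
        if set(self.coords) != set(LANDMARKS):
            missing = set(LANDMARKS) - set(self.coords)
            extra = set(self.coords) - set(LANDMARKS)
            raise GeometryError(
                f"marker set must contain exactly {LANDMARKS}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        xs = [self.coords[name][0] for name in LANDMARKS]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise GeometryError(
                "landmark x positions must be strictly increasing in the "
                f"craniocaudal order {LANDMARKS}; got {xs}"
            )
        for name in LANDMARKS:
            if self.coords[name][1] < 0:
                raise GeometryError(f"landmark {name} lies below the support surface")

    def xy(self, name: str) -> tuple[float, float]:
        return self.coords[name]

    def as_array(self) -> np.ndarray:
        """(5, 2) array of (x, y) in landmark order."""
        return np.array([self.coords[name] for name in LANDMARKS], dtype=float)


def load_frame(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG and return the first channel as float64."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img, dtype=float)


def detect_markers(frame, expected_n: int = 5) -> list[DetectedMarker]:
    """Segment dark circular markers on a light background.

    Otsu threshold -> connected components -> circularity filter
    (4*pi*A/P^2 >= 0.6).  Centers are intensity-weighted centroids of the
    marker darkness; the diameter is the equivalent-area circle diameter
    of the darkness-weighted blob area, which keeps sub-pixel accuracy on
    anti-aliased circles.  Markers are ranked by circularity x area and
    the top ``expected_n`` returned, ties broken by smaller center_x.

    Raises :class:`DetectionError` if fewer than ``expected_n`` candidate
    blobs survive the filter.
    """
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=float)
    if pixels.ndim != 2:
        raise DetectionError("expected a single-channel raster")

    if np.ptp(pixels) == 0:
        raise DetectionError("found 0 markers in a constant frame", n_found=0)
    thresh = threshold_otsu(pixels)
    mask = pixels < thresh
    labels = label(mask)

    candidates: list[DetectedMarker] = []
    nrows, ncols = pixels.shape
    pad = 3
    for region in regionprops(labels):
        if region.area < _MIN_BLOB_AREA_PX:
            continue
        perimeter = region.perimeter
        if perimeter <= 0:
            continue
        circularity = min(1.0, 4.0 * np.pi * region.area / perimeter**2)
        if circularity < _MIN_CIRCULARITY:
            continue

        # Measure center and area on a coverage map over a padded box so
        # anti-aliased boundary pixels below the threshold still count
        # fractionally; this keeps the diameter sub-pixel accurate.
        minr, minc, maxr, maxc = region.bbox
        r0, r1 = max(minr - pad, 0), min(maxr + pad, nrows)
        c0, c1 = max(minc - pad, 0), min(maxc + pad, ncols)
        box = pixels[r0:r1, c0:c1]
        box_labels = labels[r0:r1, c0:c1]
        bg_px = box[box >= thresh]
        bg = float(np.median(bg_px)) if bg_px.size else float(pixels.max())
        fg = float(box[box_labels == region.label].min())
        if bg <= fg:
            continue
        coverage = (bg - box) / (bg - fg)
        coverage[(box_labels != 0) & (box_labels != region.label)] = 0.0
        total = float(coverage.sum())
        if total <= 0:
            continue
        ys, xs = np.mgrid[r0:r1, c0:c1]
        cy = float((coverage * ys).sum() / total)
        cx = float((coverage * xs).sum() / total)
        diameter = 2.0 * np.sqrt(total / np.pi)
        candidates.append(
            DetectedMarker(
                center_x=cx,
                center_y=cy,
                diameter=diameter,
                circularity=float(circularity),
            )
        )

    if len(candidates) < expected_n:
        raise DetectionError(
            f"found {len(candidates)} circular markers, expected {expected_n}",
            n_found=len(candidates),
        )
    candidates.sort(key=lambda m: (-m.score, m.center_x))
    return candidates[:expected_n]


def calibrate(
    markers: list[DetectedMarker],
    reference_diameter_mm: float = MARKER_DIAMETER_MM,
) -> Calibration:
    """Metric scale from the known marker diameter.

    mm_per_px = reference diameter / median detected diameter; the median
    is robust to one badly segmented marker.
    """
    if not markers:
        raise CalibrationError("calibration requires at least one detected marker")
    diameters = np.array([m.diameter for m in markers], dtype=float)
    if np.any(diameters <= 0):
        raise CalibrationError("all detected diameters must be positive")
    return Calibration(
        mm_per_px=reference_diameter_mm / float(np.median(diameters)),
        reference_diameter_mm=reference_diameter_mm,
    )


def assign_landmarks(
    markers: list[DetectedMarker],
    cal: Calibration,
    baseline_y_px: float,
    axis_direction: str = "x_increasing_caudal",
) -> MarkerSet:
    """Label five detections MEd..EId along the body axis and calibrate.

    ``baseline_y_px`` is the image row of the support surface; physical y
    is measured upward from it.  ``axis_direction`` states whether the
    caudal direction corresponds to increasing or decreasing image x.
    """
    if len(markers) != 5:
        raise DetectionError(f"landmark assignment needs exactly 5 markers, got {len(markers)}")
    if axis_direction not in ("x_increasing_caudal", "x_decreasing_caudal"):
        raise ParameterError(f"unknown axis_direction {axis_direction!r}")

    reverse = axis_direction == "x_decreasing_caudal"
    ordered = sorted(markers, key=lambda m: -m.center_x if reverse else m.center_x)
    xs = [m.center_x for m in ordered]
    if any(abs(x2 - x1) < 2.0 for x1, x2 in zip(xs, xs[1:])):
        raise GeometryError(
            "two markers within 2 px along the body axis: craniocaudal ordering is ambiguous"
        )

    x0 = ordered[0].center_x
    coords = {}
    for name, m in zip(LANDMARKS, ordered):
        dx_px = (x0 - m.center_x) if reverse else (m.center_x - x0)
        x_cm = cal.px_to_cm(dx_px)
        y_cm = cal.px_to_cm(baseline_y_px - m.center_y)  # image rows grow downward
        if y_cm < 0:
            raise GeometryError(f"marker for {name} lies below the supplied baseline row")
        coords[name] = (x_cm, y_cm)
    return MarkerSet(coords=coords, source="detected")


def read_marker_csv(path: str | Path) -> dict[tuple[str, str], list[dict]]:
    """Read a manually digitized coordinate table.

    Expected columns: subject_id, phase, landmark, x_px, y_px, diameter_px
    (header required, UTF-8).  Returns rows grouped by (subject_id, phase).
    """
    required = {"subject_id", "phase", "landmark", "x_px", "y_px", "diameter_px"}
    groups: dict[tuple[str, str], list[dict]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(
                f"coordinate CSV must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            key = (row["subject_id"], row["phase"])
            groups.setdefault(key, []).append(
                {
                    "landmark": row["landmark"],
                    "x_px": float(row["x_px"]),
                    "y_px": float(row["y_px"]),
                    "diameter_px": float(row["diameter_px"]),
                }
            )
    return groups


def markerset_from_manual(
    rows: list[dict],
    baseline_y_px: float,
    axis_direction: str = "x_increasing_caudal",
    reference_diameter_mm: float = MARKER_DIAMETER_MM,
) -> MarkerSet:
    """Build a calibrated MarkerSet from manually digitized pixel rows."""
    if len(rows) != 5:
        raise SchemaError(f"expected 5 landmark rows per subject/phase, got {len(rows)}")
    markers = [
        DetectedMarker(
            center_x=r["x_px"], center_y=r["y_px"], diameter=r["diameter_px"], circularity=1.0
        )
        for r in rows
    ]
    cal = calibrate(markers, reference_diameter_mm)
    ms = assign_landmarks(markers, cal, baseline_y_px, axis_direction)
    # manual rows carry their own landmark labels; verify against axis order
    by_x = sorted(rows, key=lambda r: r["x_px"], reverse=axis_direction == "x_decreasing_caudal")
    labels = [r["landmark"] for r in by_x]
    if labels != list(LANDMARKS):
        raise SchemaError(
            f"manual landmark labels {labels} do not match craniocaudal order {list(LANDMARKS)}"
        )
    return MarkerSet(coords=ms.coords, source="manual")
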