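"""Compartmental thoracoabdominal volumetry by 2D-to-3D extrusion.

The sagittal trunk profile of a supine subject is partitioned by the five
landmarks into four compartments: upper thorax (UT, MEd-AXd), lower thorax
(LT, AXd-ACd), upper abdomen (UA, ACd-COd) and lower abdomen (LA, COd-EId).
Each compartment is the trapezoid bounded above by the straight segment
joining two adjacent landmarks, below by the support surface (y = 0), and
laterally by the vertical feet dropped from the landmarks.  Areas (cm^2)
are extruded by the caliper-measured thorax length (cm) into volumes
(litres).  The difference between the inspiration and expiration
thoracoabdominal totals is the total volumetric mobility, the kinematic
predictor used by the regression equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .imaging import LANDMARKS, MarkerSet

log = logging.getLogger(__name__)

#: Compartment -> (cranial landmark, caudal landmark)
COMPARTMENT_BOUNDS = {
    "UT": ("MEd", "AXd"),
    "LT": ("AXd", "ACd"),
    "UA": ("ACd", "COd"),
    "LA": ("COd", "EId"),
}
COMPARTMENTS = tuple(COMPARTMENT_BOUNDS)

_ATOL = 1e-9


@dataclass(frozen=True)
class CompartmentAreas:
    """Sagittal profile areas of the four compartments, in cm^2."""

    UT: float
    LT: float
    UA: float
    LA: float

    def __post_init__(self):
        for name in COMPARTMENTS:
            if getattr(self, name) < 0:
                raise GeometryError(f"compartment area {name} is negative")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPARTMENTS}


@dataclass(frozen=True)
class CompartmentVolumes:
    """Extruded compartment volumes in litres, with additive totals.

    TT = UT + LT (total thorax), TA = UA + LA (total abdomen) and
    thoracoabdominal = TT + TA hold exactly by construction.
    """

    UT: float
    LT: float
    TT: float
    UA: float
    LA: float
    TA: float
    thoracoabdominal: float

    def __post_init__(self):
        for name in ("UT", "LT", "TT", "UA", "LA", "TA", "thoracoabdominal"):
            if getattr(self, name) < 0:
                raise GeometryError(f"volume {name} is negative")
        if abs(self.TT - (self.UT + self.LT)) > _ATOL:
            raise GeometryError("TT must equal UT + LT")
        if abs(self.TA - (self.UA + self.LA)) > _ATOL:
            raise GeometryError("TA must equal UA + LA")
        if abs(self.thoracoabdominal - (self.TT + self.TA)) > _ATOL:
            raise GeometryError("thoracoabdominal must equal TT + TA")

    @classmethod
    def from_compartments(cls, UT: float, LT: float, UA: float, LA: float) -> "CompartmentVolumes":
        return cls(
            UT=UT,
            LT=LT,
            TT=UT + LT,
            UA=UA,
            LA=LA,
            TA=UA + LA,
            thoracoabdominal=(UT + LT) + (UA + LA),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in ("UT", "LT", "TT", "UA", "LA", "TA", "thoracoabdominal")
        }


@dataclass(frozen=True)
class BreathPair:
    """Expiration and inspiration volumes with the derived mobility."""

    expiration: CompartmentVolumes
    inspiration: CompartmentVolumes
    mobility: float

    def __post_init__(self):
        expected = self.inspiration.thoracoabdominal - self.expiration.thoracoabdominal
        if abs(self.mobility - expected) > _ATOL:
            raise GeometryError("mobility must equal inspiration minus expiration total")


def _segments_properly_intersect(p1, p2, p3, p4) -> bool:
    """True when segments p1p2 and p3p4 cross at an interior point."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return d1 * d2 < 0 and d3 * d4 < 0


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a simple polygon.

    Raises :class:`GeometryError` for fewer than three vertices or when
    two non-adjacent edges properly cross.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    n = pts.shape[0]
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share an endpoint
            if _segments_properly_intersect(*edges[i], *edges[j]):
                raise GeometryError(f"polygon edges {i} and {j} intersect: not a simple polygon")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def build_compartments(markers: MarkerSet) -> CompartmentAreas:
    """Areas of the four baseline-closed trapezoids under the profile."""
    areas = {}
    for comp, (a, b) in COMPARTMENT_BOUNDS.items():
        (x1, y1), (x2, y2) = markers.xy(a), markers.xy(b)
        if x2 <= x1:
            raise GeometryError(
                f"craniocaudal ordering violated between {a} and {b} ({x1} >= {x2})"
            )
        quad = [(x1, 0.0), (x1, y1), (x2, y2), (x2, 0.0)]
        # drop duplicate vertices from zero-height landmarks
        dedup = [quad[0]]
        for p in quad[1:]:
            if p != dedup[-1]:
                dedup.append(p)
        areas[comp] = polygon_area(dedup) if len(dedup) >= 3 else 0.0
    return CompartmentAreas(**areas)


def extrude(areas: CompartmentAreas, thorax_length: float) -> CompartmentVolumes:
    """Sweep each profile area through the thorax length: litres = cm^2 * cm / 1000."""
    if thorax_length <= 0:
        raise ParameterError("thorax_length must be positive (cm)")
    litres = {name: area * thorax_length / 1000.0 for name, area in areas.as_dict().items()}
    return CompartmentVolumes.from_compartments(**litres)


def volumes_from_markers(markers: MarkerSet, thorax_length: float) -> CompartmentVolumes:
    """Convenience: compartment areas then extrusion in one call."""
    return extrude(build_compartments(markers), thorax_length)


def pair_breath(exp: CompartmentVolumes, insp: CompartmentVolumes) -> BreathPair:
    """Combine the two extreme phases; mobility = insp − exp total.

    A negative mobility (inspiration smaller than expiration) is returned
    as-is with a warning, since it indicates mislabeled phases.
    """
    mobility = insp.thoracoabdominal - exp.thoracoabdominal
    if mobility < 0:
        log.warning(
            "inspiration total (%.3f l) below expiration total (%.3f l): negative mobility",
            insp.thoracoabdominal,
            exp.thoracoabdominal,
        )
    return BreathPair(expiration=exp, inspiration=insp, mobility=mobility)


def variability_percent(exp_vol: float, insp_vol: float) -> float:
    """Relative inspiration-expiration change of one compartment, in %.

    Reported to one decimal, matching how compartmental recruitment is
    conventionally quoted.
    """
    if exp_vol <= 0:
        raise ParameterError("expiration volume must be positive")
    return round(100.0 * (insp_vol - exp_vol) / exp_vol, 1)


def compartment_share(vol: CompartmentVolumes) -> tuple[float, float]:
    """Percent contribution of total thorax and total abdomen to the trunk total."""
    if vol.thoracoabdominal <= 0:
        raise ParameterError("thoracoabdominal total must be positive")
    tt = round(100.0 * vol.TT / vol.thoracoabdominal, 1)
    ta = round(100.0 * vol.TA / vol.thoracoabdominal, 1)
    return tt, ta
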