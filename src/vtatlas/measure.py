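"""Landmark-based vocal-tract measurements and cohort summary statistics.

The measurements follow the manual protocol on static midsagittal
images: a line is drawn from the outer touching point of the lips
toward the anterior lower border of the body of the axis vertebra (C2);
its segment up to the first intersection with the pharyngeal wall is
the buccal cavity length.  A parallel line tangent to the palate
intersects the pharyngeal wall at the upper vocal-tract boundary; the
lower boundary is the upper end of the esophagus at the level of the
vocal folds; the distance between the boundaries is the vocal-tract
height.  The width is how much of the tract is visible across the
parallel sagittal slices, in mm of slice thickness (fractional
visibility is allowed).  Landmarks are inputs in mm; no automatic
anatomy detection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "LandmarkSet",
    "VTMeasurement",
    "CohortSummary",
    "buccal_length",
    "vt_height",
    "vt_width",
    "cohort_summary",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Manual landmarks in mm (image-frame coordinates)."""

    lip_contact_point: tuple[float, float]
    axis_vertebra_point: tuple[float, float]
    palate_tangent_point: tuple[float, float]
    vocal_fold_point: tuple[float, float]
    esophagus_point: tuple[float, float]
    pharyngeal_wall: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = [
            self.lip_contact_point,
            self.axis_vertebra_point,
            self.palate_tangent_point,
            self.vocal_fold_point,
            self.esophagus_point,
            *self.pharyngeal_wall,
        ]
        if len(self.pharyngeal_wall) < 2:
            raise ValueError("pharyngeal wall polyline needs >= 2 vertices")
        if not np.all(np.isfinite(np.asarray(pts, dtype=float))):
            raise ValueError("landmark coordinates must be finite")


@dataclass(frozen=True)
class VTMeasurement:
    """Vocal-tract dimensions of one speaker, in mm."""

    speaker_id: str
    length_mm: float
    height_mm: float
    width_mm: float

    def __post_init__(self):
        if min(self.length_mm, self.height_mm, self.width_mm) <= 0:
            raise ValueError("measurements must be positive")


def _first_intersection(
    origin: tuple[float, float],
    direction: np.ndarray,
    wall: tuple[tuple[float, float], ...],
    reach: float = 1e4,
) -> np.ndarray:
    """First crossing of the ray origin + s*direction with the wall."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate (zero-length) measurement line")
    ray = LineString([o, o + d / norm * reach])
    inter = ray.intersection(LineString(wall))
    if inter.is_empty:
        raise ValueError("measurement line does not intersect the pharyngeal wall")
    pts = (
        [inter]
        if isinstance(inter, Point)
        else [g for g in getattr(inter, "geoms", [inter]) if isinstance(g, Point)]
    )
    if not pts:  # collinear overlap: take nearest point of the overlap
        pts = [Point(c) for c in inter.coords]
    best = min(pts, key=lambda p: p.distance(Point(o)))
    return np.array([best.x, best.y])


def buccal_length(lm: LandmarkSet) -> float:
    """Length (mm) from the lips to the pharyngeal wall along the
    lips→axis-vertebra line."""
    lips = np.asarray(lm.lip_contact_point, dtype=float)
    axis = np.asarray(lm.axis_vertebra_point, dtype=float)
    hit = _first_intersection(lm.lip_contact_point, axis - lips, lm.pharyngeal_wall)
    return float(np.linalg.norm(hit - lips))


def vt_height(lm: LandmarkSet) -> float:
    """Height (mm): distance between the upper boundary (palate-parallel
    line meets the pharyngeal wall) and the lower boundary (esophagus)."""
    lips = np.asarray(lm.lip_contact_point, dtype=float)
    axis = np.asarray(lm.axis_vertebra_point, dtype=float)
    upper = _first_intersection(lm.palate_tangent_point, axis - lips, lm.pharyngeal_wall)
    lower = np.asarray(lm.esophagus_point, dtype=float)
    return float(np.linalg.norm(upper - lower))


def vt_width(visible_fraction: "list[float]", slice_thickness_mm: float = 8.0) -> float:
    """Width (mm): summed fractional slice visibility times thickness.

    A fully visible tract across all 5 planes of 8 mm gives 40 mm;
    fractional visibility accommodates widths that are not multiples of
    the slice thickness.
    """
    fr = np.asarray(visible_fraction, dtype=float)
    if np.any(fr < 0) or np.any(fr > 1):
        raise ValueError("visible fractions must lie in [0, 1]")
    return float(fr.sum() * slice_thickness_mm)


@dataclass(frozen=True)
class CohortSummary:
    """Mean, population SD and range per dimension, in mm."""

    mean: dict[str, float]
    sd: dict[str, float]
    range: dict[str, float]


def cohort_summary(measurements: "list[VTMeasurement]") -> CohortSummary:
    """Cohort statistics: mean, population SD (÷n) and max−min range.

    The population SD convention (÷n rather than ÷(n−1)) matches the
    reporting convention of the study protocol this module mirrors.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    dims = {
        "length": np.array([m.length_mm for m in measurements], dtype=float),
        "height": np.array([m.height_mm for m in measurements], dtype=float),
        "width": np.array([m.width_mm for m in measurements], dtype=float),
    }
    return CohortSummary(
        mean={k: float(v.mean()) for k, v in dims.items()},
        sd={k: float(v.std(ddof=0)) for k, v in dims.items()},
        range={k: float(v.max() - v.min()) for k, v in dims.items()},
    )
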