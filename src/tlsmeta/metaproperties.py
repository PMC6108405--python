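"""The six scan metaproperties and the per-scan feature vector.

A *metaproperty* is a population-level statistic of all pulses in one scan.
Three are pulse metaproperties computed over the hemisphere above the
optical plane (zenith ≤ 90°):

- ``mean_distance`` — mean distance to first returns (m);
- ``mean_intensity`` — mean intensity of first returns;
- ``first_second_ratio`` — count of first returns : count of second returns.

Three are spatial metaproperties, geometric attributes of the empty space a
scan reveals:

- ``no_return_ratio`` — pulses with no return : pulses emitted, in the
  30°–35° zenith band (a gap-fraction analogue);
- ``opa`` — optical plane area (m²): area of the polygon joining the (x, y)
  positions of first returns from pulses emitted at the optical plane
  (zenith = 90°), vertices in azimuth order;
- ``rugosity`` — ratio of the Delaunay-triangulated 3-D surface area fitted
  to first returns in the 0°–30° zenith band to the area of their planar
  (x, y) footprint; 1 for a flat surface, larger for structured canopies.

Metrics that cannot be computed for a scan (empty band, too few polygon
vertices, zero second returns) are flagged rather than silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import NotComputableError, ValidationError
from .scan import Scan, spherical_to_cartesian

__all__ = [
    "MetapropertyConfig",
    "MetapropertyVector",
    "METRIC_NAMES",
    "mean_distance",
    "mean_intensity",
    "first_second_ratio",
    "no_return_ratio",
    "optical_plane_area",
    "rugosity",
    "extract_all",
    "extract_table",
    "polygon_area",
]

METRIC_NAMES = [
    "mean_distance",
    "mean_intensity",
    "first_second_ratio",
    "no_return_ratio",
    "opa",
    "rugosity",
]


@dataclass(frozen=True)
class MetapropertyConfig:
    """Zenith-band definitions for the six metaproperties.

    ``optical_plane_tolerance_deg`` is the half-width of the "zenith = 90°"
    band: real scans sample discrete zenith rows, so the optical plane is
    taken as the row(s) within this tolerance of 90°.
    """

    pulse_band: tuple = (0.0, 90.0)
    gap_band: tuple = (30.0, 35.0)
    rugosity_band: tuple = (0.0, 30.0)
    optical_plane_tolerance_deg: float = 0.5
    min_polygon_vertices: int = 3

    def __post_init__(self):
        for band in (self.pulse_band, self.gap_band, self.rugosity_band):
            lo, hi = band
            if not (0.0 <= lo <= hi <= 180.0):
                raise ValidationError(f"zenith band {band} outside [0, 180]")
        if not self.optical_plane_tolerance_deg > 0:
            raise ValidationError("optical plane tolerance must be > 0")
        if self.min_polygon_vertices < 3:
            raise ValidationError("a polygon needs at least 3 vertices")


@dataclass
class MetapropertyVector:
    """The six metaproperties of one scan; the feature row for classification.

    ``flags`` records, per metric, why a value is missing or degenerate
    (e.g. ``"no second returns"`` on an infinite first:second ratio).
    Missing metrics are NaN; the infinite ratio sentinel is ``math.inf``.
    """

    scan_id: object
    label: object = None
    mean_distance: float = math.nan
    mean_intensity: float = math.nan
    first_second_ratio: float = math.nan
    no_return_ratio: float = math.nan
    opa: float = math.nan
    rugosity: float = math.nan
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"scan_id": self.scan_id, "label": self.label}
        for name in METRIC_NAMES:
            d[name] = getattr(self, name)
        return d


# -- pulse metaproperties ---------------------------------------------------

def _first_return_mask(scan: Scan, band) -> np.ndarray:
    return scan.band_mask(*band) & scan.has_return


def mean_distance(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> float:
    """Mean distance (m) to first returns above the optical plane."""
    scan.require_pulses()
    m = _first_return_mask(scan, config.pulse_band)
    if not m.any():
        raise NotComputableError(
            f"scan {scan.scan_id!r}: no first returns in zenith band {config.pulse_band}")
    return float(scan.r1_distance[m].mean())


def mean_intensity(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> float:
    """Mean intensity of first returns above the optical plane."""
    scan.require_pulses()
    m = _first_return_mask(scan, config.pulse_band)
    if not m.any():
        raise NotComputableError(
            f"scan {scan.scan_id!r}: no first returns in zenith band {config.pulse_band}")
    return float(scan.r1_intensity[m].mean())


def first_second_ratio(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> float:
    """Ratio of first-return count to second-return count above the optical plane.

    Returns ``math.inf`` when the scan has first returns but no second
    returns in the band (the caller is expected to flag the value; it must
    not be log-transformed).
    """
    scan.require_pulses()
    band = scan.band_mask(*config.pulse_band)
    n1 = int(np.count_nonzero(band & ~np.isnan(scan.r1_distance)))
    n2 = int(np.count_nonzero(band & ~np.isnan(scan.r2_distance)))
    if n1 == 0:
        raise NotComputableError(
            f"scan {scan.scan_id!r}: no first returns in zenith band {config.pulse_band}")
    if n2 == 0:
        return math.inf
    return n1 / n2


# -- spatial metaproperties -------------------------------------------------

def no_return_ratio(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> float:
    """Fraction of pulses with no return in the gap band (default 30°–35°)."""
    scan.require_pulses()
    band = scan.band_mask(*config.gap_band)
    n = int(np.count_nonzero(band))
    if n == 0:
        raise NotComputableError(
            f"scan {scan.scan_id!r}: no pulses in zenith band {config.gap_band}")
    n_gap = int(np.count_nonzero(band & ~scan.has_return))
    return n_gap / n


def polygon_area(x: np.ndarray, y: np.ndarray) -> float:
    """Shoelace area of the closed polygon with vertices in the given order."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("polygon area needs at least 3 vertices")
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def optical_plane_area(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> float:
    """Area (m²) of the polygon joining (x, y) first returns at the optical plane.

    Vertices are ordered by azimuth (ties broken by ascending distance), the
    polygon is closed from the last vertex back to the first, and the area is
    the absolute shoelace sum over 2.  Optical-plane pulses without returns
    contribute no vertex.
    """
    scan.require_pulses()
    tol = config.optical_plane_tolerance_deg
    m = (np.abs(scan.zenith_deg - 90.0) <= tol) & scan.has_return
    if np.count_nonzero(m) < config.min_polygon_vertices:
        raise NotComputableError(
            f"scan {scan.scan_id!r}: fewer than {config.min_polygon_vertices} "
            "first returns at the optical plane")
    d = scan.r1_distance[m]
    zen = scan.zenith_deg[m]
    az = scan.azimuth_deg[m]
    order = np.lexsort((d, az))
    x, y, _ = spherical_to_cartesian(d[order], zen[order], az[order])
    return polygon_area(x, y)


def _triangulated_areas(x, y, z):
    """(3-D surface area over Delaunay triangles, footprint hull area)."""
    pts2 = np.column_stack([x, y])
    try:
        tri = Delaunay(pts2)
    except QhullError as exc:
        raise NotComputableError(f"degenerate footprint for triangulation: {exc}") from exc
    if tri.simplices.size == 0:
        raise NotComputableError("triangulation produced no triangles")
    p = np.column_stack([x, y, z])[tri.simplices]  # (ntri, 3, 3)
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area3d = 0.5 * np.linalg.norm(cross, axis=1).sum()
    area2d = ConvexHull(pts2).volume  # 2-D "volume" is the hull area
    return float(area3d), float(area2d)


def rugosity(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> float:
    """Surface rugosity of first returns in the rugosity band (default 0°–30°).

    The Delaunay triangulation is built on the (x, y) projections; each
    triangle is lifted to its vertices' z values and the summed 3-D area is
    divided by the planar footprint area (the convex hull of the projected
    points, which coincides with the triangulated region).  The result is
    ≥ 1, with equality for a flat surface.
    """
    scan.require_pulses()
    m = _first_return_mask(scan, config.rugosity_band)
    if np.count_nonzero(m) < 3:
        raise NotComputableError(
            f"scan {scan.scan_id!r}: fewer than 3 first returns in zenith band "
            f"{config.rugosity_band}")
    x, y, z = spherical_to_cartesian(scan.r1_distance[m], scan.zenith_deg[m],
                                     scan.azimuth_deg[m])
    area3d, area2d = _triangulated_areas(x, y, z)
    if area2d <= 0:
        raise NotComputableError(
            f"scan {scan.scan_id!r}: collinear projected returns, zero footprint")
    return area3d / area2d


# -- orchestration ----------------------------------------------------------

_METRIC_FNS = {
    "mean_distance": mean_distance,
    "mean_intensity": mean_intensity,
    "first_second_ratio": first_second_ratio,
    "no_return_ratio": no_return_ratio,
    "opa": optical_plane_area,
    "rugosity": rugosity,
}


def extract_all(scan: Scan, config: MetapropertyConfig = MetapropertyConfig()) -> MetapropertyVector:
    """Compute all six metaproperties; non-computable metrics are flagged NaN."""
    if scan.n_pulses == 0:
        raise ValidationError(f"scan {scan.scan_id!r} is empty")
    vec = MetapropertyVector(scan_id=scan.scan_id, label=scan.label)
    for name, fn in _METRIC_FNS.items():
        try:
            value = fn(scan, config)
        except NotComputableError as exc:
            vec.flags[name] = str(exc)
            continue
        if name == "first_second_ratio" and math.isinf(value):
            vec.flags[name] = "no second returns (infinite ratio)"
        setattr(vec, name, value)
    return vec


def extract_table(scans: Sequence[Scan],
                  config: MetapropertyConfig = MetapropertyConfig()) -> pd.DataFrame:
    """One metaproperty row per scan, order preserved.

    Columns: ``scan_id, label, mean_distance, mean_intensity,
    first_second_ratio, no_return_ratio, opa, rugosity``.  Flagged-missing
    metrics are NaN (written as empty CSV cells); the infinite
    first:second sentinel is ``inf``.
    """
    rows = [extract_all(s, config).as_dict() for s in scans]
    return pd.DataFrame(rows, columns=["scan_id", "label"] + METRIC_NAMES)
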