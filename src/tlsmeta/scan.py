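"""Pulse-level data model and I/O for terrestrial laser scanner (TLS) scans.

A scan is the population of pulses emitted from one instrument position over
a zenith/azimuth grid.  Each pulse records up to two ranged returns (distance
from the optical centre, relative intensity).  The zenith convention is
0° = vertically up, 90° = the horizontal optical plane; azimuth is measured
counterclockwise from +x viewed from above.  All coordinates are
sensor-relative: the origin is the optical centre, z points up.

Internally a :class:`Scan` stores pulses columnar (NumPy arrays, one slot per
pulse with NaN marking an absent return) so that population metrics can be
vectorized; :class:`PulseRecord` objects are materialized on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, NotComputableError, ValidationError

__all__ = [
    "ReturnRecord",
    "PulseRecord",
    "InstrumentSpec",
    "CartesianPoint",
    "Scan",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "read_scan_csv",
    "write_scan_csv",
    "subset_pulses",
    "SCAN_CSV_COLUMNS",
]

SCAN_CSV_COLUMNS = [
    "pulse_id",
    "zenith_deg",
    "azimuth_deg",
    "return_index",
    "distance_m",
    "intensity",
]


@dataclass(frozen=True)
class ReturnRecord:
    """One ranged return of a pulse (index 1 = first, 2 = second)."""

    index: int
    distance: float
    intensity: float

    def __post_init__(self):
        if self.index not in (1, 2):
            raise ValidationError(f"return index must be 1 or 2, got {self.index}")
        if not self.distance > 0:
            raise ValidationError(f"return distance must be > 0, got {self.distance}")


@dataclass(frozen=True)
class PulseRecord:
    """One emitted pulse with 0-2 returns sorted by ascending distance."""

    pulse_id: object
    zenith_deg: float
    azimuth_deg: float
    returns: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.zenith_deg <= 180.0:
            raise ValidationError(
                f"zenith must be in [0, 180] degrees, got {self.zenith_deg}"
            )
        rs = tuple(self.returns)
        if len(rs) > 2:
            raise ValidationError("a pulse records at most 2 returns")
        if len(rs) == 2:
            if rs[0].index != 1 or rs[1].index != 2:
                raise ValidationError("returns must be ordered (index 1, index 2)")
            if rs[0].distance > rs[1].distance:
                raise ValidationError("returns must be sorted by ascending distance")
        object.__setattr__(self, "returns", rs)

    @property
    def n_returns(self) -> int:
        return len(self.returns)

    @property
    def first_return(self) -> Optional[ReturnRecord]:
        return self.returns[0] if self.returns else None


@dataclass(frozen=True)
class InstrumentSpec:
    """Static instrument parameters.

    Defaults follow a compact biomass lidar class of instrument: ~40 m
    maximum range, 15 mrad beam divergence, tripod-mounted optical centre at
    ~1.3 m, first and second returns recorded per pulse.
    """

    max_range_m: float = 40.0
    beam_divergence_mrad: float = 15.0
    sensor_height_m: float = 1.3
    max_returns: int = 2

    def __post_init__(self):
        for name in ("max_range_m", "beam_divergence_mrad", "sensor_height_m", "max_returns"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"instrument {name} must be strictly positive")


@dataclass(frozen=True)
class CartesianPoint:
    """Point in the sensor-relative right-handed frame (z up), meters."""

    x: float
    y: float
    z: float


class Scan:
    """A population of pulses from one instrument position.

    Parameters
    ----------
    scan_id : hashable identifier.
    pulses : sequence of :class:`PulseRecord`.
    instrument : :class:`InstrumentSpec`.
    label : optional binary class tag (0/1 or any hashable).
    metadata : free-form key/value mapping.
    """

    def __init__(self, scan_id, pulses: Sequence[PulseRecord],
                 instrument: Optional[InstrumentSpec] = None,
                 label=None, metadata: Optional[dict] = None):
        self.scan_id = scan_id
        self.instrument = instrument if instrument is not None else InstrumentSpec()
        self.label = label
        self.metadata = dict(metadata) if metadata else {}

        pulses = list(pulses)
        ids = [p.pulse_id for p in pulses]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"scan {scan_id!r}: pulse_ids are not unique")
        n = len(pulses)
        self.pulse_id = np.array(ids, dtype=object)
        self.zenith_deg = np.array([p.zenith_deg for p in pulses], dtype=float)
        self.azimuth_deg = np.array([p.azimuth_deg for p in pulses], dtype=float)
        self.r1_distance = np.full(n, np.nan)
        self.r1_intensity = np.full(n, np.nan)
        self.r2_distance = np.full(n, np.nan)
        self.r2_intensity = np.full(n, np.nan)
        for i, p in enumerate(pulses):
            for r in p.returns:
                if r.distance > self.instrument.max_range_m + 1e-9:
                    raise ValidationError(
                        f"scan {scan_id!r} pulse {p.pulse_id!r}: return distance "
                        f"{r.distance} exceeds max range {self.instrument.max_range_m}"
                    )
                if r.index == 1:
                    self.r1_distance[i] = r.distance
                    self.r1_intensity[i] = r.intensity
                else:
                    self.r2_distance[i] = r.distance
                    self.r2_intensity[i] = r.intensity

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_arrays(cls, scan_id, zenith_deg, azimuth_deg,
                    r1_distance, r1_intensity, r2_distance, r2_intensity,
                    instrument: Optional[InstrumentSpec] = None,
                    label=None, metadata=None, pulse_id=None) -> "Scan":
        """Fast columnar constructor (NaN marks an absent return)."""
        obj = cls.__new__(cls)
        obj.scan_id = scan_id
        obj.instrument = instrument if instrument is not None else InstrumentSpec()
        obj.label = label
        obj.metadata = dict(metadata) if metadata else {}
        obj.zenith_deg = np.asarray(zenith_deg, dtype=float)
        obj.azimuth_deg = np.asarray(azimuth_deg, dtype=float)
        n = obj.zenith_deg.size
        if pulse_id is None:
            pulse_id = np.array([f"p{i:06d}" for i in range(n)], dtype=object)
        obj.pulse_id = np.asarray(pulse_id, dtype=object)
        obj.r1_distance = np.asarray(r1_distance, dtype=float)
        obj.r1_intensity = np.asarray(r1_intensity, dtype=float)
        obj.r2_distance = np.asarray(r2_distance, dtype=float)
        obj.r2_intensity = np.asarray(r2_intensity, dtype=float)
        for arr in (obj.azimuth_deg, obj.r1_distance, obj.r1_intensity,
                    obj.r2_distance, obj.r2_intensity, obj.pulse_id):
            if arr.shape != obj.zenith_deg.shape:
                raise ValidationError("all columnar arrays must share one length")
        if np.any((obj.zenith_deg < 0) | (obj.zenith_deg > 180)):
            raise ValidationError("zenith angles must lie in [0, 180] degrees")
        # a second return without a first, or unsorted distances, is malformed
        orphan = np.isnan(obj.r1_distance) & ~np.isnan(obj.r2_distance)
        if np.any(orphan):
            raise ValidationError("second return present without a first return")
        both = ~np.isnan(obj.r1_distance) & ~np.isnan(obj.r2_distance)
        if np.any(obj.r1_distance[both] > obj.r2_distance[both]):
            raise ValidationError("returns must be sorted by ascending distance")
        return obj

    # -- basic queries -----------------------------------------------------

    @property
    def n_pulses(self) -> int:
        return int(self.zenith_deg.size)

    @property
    def has_return(self) -> np.ndarray:
        return ~np.isnan(self.r1_distance)

    @property
    def pulses(self) -> List[PulseRecord]:
        """Materialize all pulses as :class:`PulseRecord` objects."""
        out = []
        for i in range(self.n_pulses):
            rs = []
            if not math.isnan(self.r1_distance[i]):
                rs.append(ReturnRecord(1, float(self.r1_distance[i]),
                                       float(self.r1_intensity[i])))
            if not math.isnan(self.r2_distance[i]):
                rs.append(ReturnRecord(2, float(self.r2_distance[i]),
                                       float(self.r2_intensity[i])))
            out.append(PulseRecord(self.pulse_id[i], float(self.zenith_deg[i]),
                                   float(self.azimuth_deg[i]), tuple(rs)))
        return out

    def band_mask(self, zenith_min_deg: float, zenith_max_deg: float) -> np.ndarray:
        """Boolean mask of pulses inside the closed zenith interval."""
        if zenith_min_deg > zenith_max_deg:
            raise ValidationError(
                f"inverted zenith bounds [{zenith_min_deg}, {zenith_max_deg}]"
            )
        return (self.zenith_deg >= zenith_min_deg) & (self.zenith_deg <= zenith_max_deg)

    def require_pulses(self):
        if self.n_pulses == 0:
            raise NotComputableError(
                f"scan {self.scan_id!r} has no pulses; metaproperties undefined"
            )


# -- spherical / Cartesian conversions -------------------------------------

def spherical_to_cartesian(distance, zenith_deg, azimuth_deg):
    """Convert spherical scan coordinates to sensor-relative Cartesian.

    x = d sin(zen) cos(az), y = d sin(zen) sin(az), z = d cos(zen).
    Accepts scalars or arrays; scalars return a :class:`CartesianPoint`.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("distance must be strictly positive")
    zen = np.deg2rad(np.asarray(zenith_deg, dtype=float))
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    x = d * np.sin(zen) * np.cos(az)
    y = d * np.sin(zen) * np.sin(az)
    z = d * np.cos(zen)
    if x.ndim == 0:
        return CartesianPoint(float(x), float(y), float(z))
    return x, y, z


def cartesian_to_spherical(x, y, z):
    """Inverse of :func:`spherical_to_cartesian`; returns (d, zenith°, azimuth°)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    d = np.sqrt(x * x + y * y + z * z)
    if np.any(d <= 0):
        raise ValidationError("point at the origin has no spherical direction")
    zen = np.rad2deg(np.arccos(np.clip(z / d, -1.0, 1.0)))
    az = np.rad2deg(np.arctan2(y, x)) % 360.0
    if d.ndim == 0:
        return float(d), float(zen), float(az)
    return d, zen, az


# -- subsetting -------------------------------------------------------------

_RETURN_FILTERS = ("all", "first_only", "with_any_return", "no_return")


def subset_pulses(scan: Scan, zenith_min_deg: float, zenith_max_deg: float,
                  return_filter: str = "all") -> List[PulseRecord]:
    """Pulses inside the closed zenith band, passing the return filter.

    ``first_only`` and ``with_any_return`` both select pulses that recorded at
    least one return (every returned pulse has a first return);
    ``no_return`` selects pulses that recorded none.  Original pulse order is
    preserved.
    """
    if return_filter not in _RETURN_FILTERS:
        raise ValidationError(
            f"unknown return filter {return_filter!r}; expected one of {_RETURN_FILTERS}"
        )
    mask = scan.band_mask(zenith_min_deg, zenith_max_deg)
    if return_filter in ("first_only", "with_any_return"):
        mask &= scan.has_return
    elif return_filter == "no_return":
        mask &= ~scan.has_return
    idx = np.flatnonzero(mask)
    pulses = scan.pulses
    return [pulses[i] for i in idx]


# -- CSV I/O ----------------------------------------------------------------

def read_scan_csv(path, instrument: Optional[InstrumentSpec] = None,
                  scan_id=None, label=None) -> Scan:
    """Read a scan from the long CSV dialect (one row per return).

    Header ``pulse_id,zenith_deg,azimuth_deg,return_index,distance_m,intensity``
    is required; ``return_index`` 0 with empty distance/intensity marks a
    pulse that produced no return.  Malformed rows are reported with their
    1-based file line numbers.
    """
    instrument = instrument if instrument is not None else InstrumentSpec()
    try:
        df = pd.read_csv(path, dtype={"pulse_id": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable scan CSV ({exc})") from exc
    missing = [c for c in SCAN_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    lines = df.index.to_numpy() + 2  # 1-based, after the header line
    bad = []

    def _flag(mask, why):
        for ln in lines[np.asarray(mask)][:5]:
            bad.append(f"line {ln}: {why}")

    zen = pd.to_numeric(df["zenith_deg"], errors="coerce").to_numpy()
    az = pd.to_numeric(df["azimuth_deg"], errors="coerce").to_numpy()
    ridx = pd.to_numeric(df["return_index"], errors="coerce").to_numpy()
    dist = pd.to_numeric(df["distance_m"], errors="coerce").to_numpy()
    inten = pd.to_numeric(df["intensity"], errors="coerce").to_numpy()

    _flag(np.isnan(zen) | (zen < 0) | (zen > 180), "zenith outside [0, 180]")
    _flag(np.isnan(az), "non-numeric azimuth")
    _flag(np.isnan(ridx) | ~np.isin(ridx, (0, 1, 2)), "return_index not in {0, 1, 2}")
    ranged = np.isin(ridx, (1, 2))
    _flag(ranged & (np.isnan(dist) | (dist <= 0)), "non-positive or missing distance")
    _flag(ranged & (dist > instrument.max_range_m + 1e-9),
          f"distance exceeds max range {instrument.max_range_m} m")
    if bad:
        raise ValidationError(f"{path}: malformed rows: " + "; ".join(bad))

    if scan_id is None:
        import os
        scan_id = os.path.splitext(os.path.basename(str(path)))[0]

    if len(df) == 0:
        return Scan.from_arrays(scan_id, [], [], [], [], [], [],
                                instrument=instrument, label=label, pulse_id=[])

    # one slot per pulse, in order of first appearance
    pid = df["pulse_id"].to_numpy()
    order, first_pos = np.unique(pid, return_index=True)
    first_pos.sort()
    upid = pid[first_pos]
    slot = {u: i for i, u in enumerate(upid)}
    n = len(upid)
    out = {
        "zen": np.full(n, np.nan), "az": np.full(n, np.nan),
        "d1": np.full(n, np.nan), "i1": np.full(n, np.nan),
        "d2": np.full(n, np.nan), "i2": np.full(n, np.nan),
    }
    for row in range(len(df)):
        i = slot[pid[row]]
        out["zen"][i] = zen[row]
        out["az"][i] = az[row]
        if ridx[row] == 1:
            if not np.isnan(out["d1"][i]):
                raise ValidationError(
                    f"{path}: line {lines[row]}: duplicate first return for "
                    f"pulse {pid[row]!r}")
            out["d1"][i], out["i1"][i] = dist[row], inten[row]
        elif ridx[row] == 2:
            if not np.isnan(out["d2"][i]):
                raise ValidationError(
                    f"{path}: line {lines[row]}: duplicate second return for "
                    f"pulse {pid[row]!r}")
            out["d2"][i], out["i2"][i] = dist[row], inten[row]
    return Scan.from_arrays(scan_id, out["zen"], out["az"],
                            out["d1"], out["i1"], out["d2"], out["i2"],
                            instrument=instrument, label=label,
                            pulse_id=upid.astype(object))


def write_scan_csv(scan: Scan, path) -> object:
    """Write a scan in the long CSV dialect; lossless to ~12 significant digits."""
    rows = {c: [] for c in SCAN_CSV_COLUMNS}

    def _push(pid, zen, az, idx, d, i):
        rows["pulse_id"].append(pid)
        rows["zenith_deg"].append(zen)
        rows["azimuth_deg"].append(az)
        rows["return_index"].append(idx)
        rows["distance_m"].append(d)
        rows["intensity"].append(i)

    for i in range(scan.n_pulses):
        pid = scan.pulse_id[i]
        zen, az = scan.zenith_deg[i], scan.azimuth_deg[i]
        if math.isnan(scan.r1_distance[i]):
            _push(pid, zen, az, 0, "", "")
        else:
            _push(pid, zen, az, 1, repr(float(scan.r1_distance[i])),
                  repr(float(scan.r1_intensity[i])))
            if not math.isnan(scan.r2_distance[i]):
                _push(pid, zen, az, 2, repr(float(scan.r2_distance[i])),
                      repr(float(scan.r2_intensity[i])))
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path
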