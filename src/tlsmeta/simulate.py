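"""Seeded ray-casting simulator of synthetic room and forest scans.

The simulator emulates the two contrasting scene archetypes that drive the
metaproperty contrasts seen in ground-based lidar:

* **Rooms** — enclosed axis-aligned boxes of continuous, hard, bright
  surfaces.  Every pulse intersects the box, so there are no gaps; second
  returns are rare (edge effects only); range noise on a flat ceiling is
  the only source of apparent 3-D structure.
* **Forests** — a fragmented canopy layer with gaps (a skyward pulse
  escapes with a configurable probability), a sparse understory modelled
  as an exponential free path, trunk cylinders, darker foliage
  reflectance, frequent partial interceptions producing second returns,
  and a hard range clip at the instrument's maximum range.

The scenes are statistical stand-ins, not radiative-transfer models: beam
divergence is not ray-sampled and partial interception is a Bernoulli
draw.  What matters for the analyses built on top is that the *population*
contrasts (gap fraction, first:second ratio, distances, intensities,
optical-plane geometry, surface rugosity) have the right direction and
magnitude, with per-scan variability, under full seeded determinism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ValidationError
from .scan import InstrumentSpec, Scan

__all__ = [
    "ScanPattern",
    "RoomSceneConfig",
    "ForestSceneConfig",
    "generate_room_scan",
    "generate_forest_scan",
    "generate_labeled_dataset",
    "ray_box_exit_distance",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "room_default",
    "forest_default",
    "forest_temperate",
    "forest_tropical",
    "forest_coastal",
    "forest_inland",
)


def load_preset(name: str):
    """Load a shipped scene preset by name; returns a scene config.

    Available presets: ``room_default``, ``forest_default`` and the
    illustrative structural variants ``forest_temperate``,
    ``forest_tropical``, ``forest_coastal``, ``forest_inland``.
    """
    import importlib.resources

    import yaml

    if name not in PRESET_NAMES:
        raise ValidationError(f"unknown preset {name!r}; one of {PRESET_NAMES}")
    ref = importlib.resources.files("tlsmeta") / "presets" / f"{name}.yaml"
    doc = yaml.safe_load(ref.read_text())
    cls = RoomSceneConfig if doc["scene"] == "room" else ForestSceneConfig
    return cls(**doc["config"])


@dataclass(frozen=True)
class ScanPattern:
    """Regular zenith × azimuth pulse grid (degrees).

    The default grid (zenith 0–130° step 1°, azimuth 0–360° step 4.5°)
    yields 131 × 80 = 10,480 pulses and includes a row at exactly 90°
    (the optical plane) plus full coverage of the 0–30° and 30–35° bands
    used by the spatial metaproperties.
    """

    zenith_start: float = 0.0
    zenith_stop: float = 130.0
    zenith_step: float = 1.0
    azimuth_start: float = 0.0
    azimuth_stop: float = 360.0
    azimuth_step: float = 4.5

    def __post_init__(self):
        if self.zenith_step <= 0 or self.azimuth_step <= 0:
            raise ValidationError("scan pattern steps must be positive")
        if self.n_pulses < 1:
            raise ValidationError("scan pattern produces no pulses")

    @property
    def zenith_values(self) -> np.ndarray:
        n = int(np.floor((self.zenith_stop - self.zenith_start) / self.zenith_step + 1e-9)) + 1
        return self.zenith_start + self.zenith_step * np.arange(n)

    @property
    def azimuth_values(self) -> np.ndarray:
        # azimuth is periodic: stop is exclusive so 0° and 360° do not repeat
        n = int(np.ceil((self.azimuth_stop - self.azimuth_start) / self.azimuth_step - 1e-9))
        return self.azimuth_start + self.azimuth_step * np.arange(max(n, 1))

    @property
    def n_pulses(self) -> int:
        return self.zenith_values.size * self.azimuth_values.size

    def grid(self) -> Tuple[np.ndarray, np.ndarray]:
        zen, az = np.meshgrid(self.zenith_values, self.azimuth_values, indexing="ij")
        return zen.ravel(), az.ravel()


@dataclass(frozen=True)
class RoomSceneConfig:
    """Axis-aligned enclosing box, sensor inside at the origin.

    ``ceiling_height`` and ``floor_depth`` are meters above/below the
    optical centre.  ``range_noise_sd_m`` defaults to 0.05 m (±50 mm range
    noise); ``second_return_prob`` is small, standing in for edge effects
    on otherwise solid surfaces.
    """

    half_width_x: float = 4.0
    half_width_y: float = 5.0
    ceiling_height: float = 2.0
    floor_depth: float = 1.3
    reflectance_mean: float = 0.75
    reflectance_sd: float = 0.05
    range_noise_sd_m: float = 0.05
    second_return_prob: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("half_width_x", "half_width_y", "ceiling_height", "floor_depth"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"room {name} must be positive "
                                      "(the sensor must sit inside the box)")
        if not 0 <= self.second_return_prob <= 1:
            raise ValidationError("second_return_prob must be in [0, 1]")


@dataclass(frozen=True)
class ForestSceneConfig:
    """Stochastic forest stand around the sensor.

    ``canopy_gap_prob`` is the probability a skyward pulse escapes through
    a canopy gap (sets the gap fraction); ``understory_density`` is the
    mean number of interceptors per meter of path below the canopy base
    (exponential free path); trunks are vertical cylinders scattered in a
    disk of ``stand_radius``.  Interceptions beyond ``max_range_clip``
    become no-returns.
    """

    canopy_base_height: float = 12.0
    canopy_top_height: float = 18.0
    canopy_gap_prob: float = 0.25
    understory_density: float = 0.05
    trunk_count: int = 12
    trunk_radius: float = 0.25
    stand_radius: float = 30.0
    second_return_prob: float = 0.25
    reflectance_mean: float = 0.35
    reflectance_sd: float = 0.08
    range_noise_sd_m: float = 0.05
    max_range_clip: float = 40.0
    ground_depth: float = 1.3
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.canopy_base_height < self.canopy_top_height:
            raise ValidationError("canopy base must lie below canopy top")
        for name in ("canopy_gap_prob", "second_return_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.understory_density < 0:
            raise ValidationError("understory_density must be >= 0")


def ray_box_exit_distance(zenith_deg, azimuth_deg, half_width_x, half_width_y,
                          ceiling_height, floor_depth) -> np.ndarray:
    """Distance from the origin to the box wall along each ray (slab method)."""
    zen = np.deg2rad(np.asarray(zenith_deg, dtype=float))
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    dx = np.sin(zen) * np.cos(az)
    dy = np.sin(zen) * np.sin(az)
    dz = np.cos(zen)
    t = np.full(zen.shape, np.inf)
    for d, lo, hi in ((dx, -half_width_x, half_width_x),
                      (dy, -half_width_y, half_width_y),
                      (dz, -floor_depth, ceiling_height)):
        with np.errstate(divide="ignore"):
            cand = np.where(d > 0, hi / d, np.where(d < 0, lo / d, np.inf))
        t = np.minimum(t, cand)
    return t


def _noisy_positive(rng, distances, sd):
    if sd <= 0:
        return distances
    noisy = distances + rng.normal(0.0, sd, size=distances.shape)
    return np.maximum(noisy, 1e-6)


def _intensities(rng, n, mean, sd):
    return np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)


def generate_room_scan(pattern: ScanPattern = ScanPattern(),
                       config: RoomSceneConfig = RoomSceneConfig(),
                       scan_id="room", seed: Optional[int] = None,
                       instrument: Optional[InstrumentSpec] = None) -> Scan:
    """Ray-cast one scan of the enclosing box; every pulse returns."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    zen, az = pattern.grid()
    exact = ray_box_exit_distance(zen, az, config.half_width_x,
                                  config.half_width_y, config.ceiling_height,
                                  config.floor_depth)
    d1 = _noisy_positive(rng, exact, config.range_noise_sd_m)
    i1 = _intensities(rng, d1.size, config.reflectance_mean, config.reflectance_sd)
    second = rng.random(d1.size) < config.second_return_prob
    d2 = np.full(d1.size, np.nan)
    i2 = np.full(d1.size, np.nan)
    # an edge splits the footprint: the second return sits just behind the first
    extra = rng.uniform(0.05, 0.5, size=int(second.sum()))
    d2[second] = d1[second] + extra
    i2[second] = _intensities(rng, int(second.sum()),
                              config.reflectance_mean * 0.5, config.reflectance_sd)
    instrument = instrument or InstrumentSpec()
    cap = instrument.max_range_m
    d1 = np.minimum(d1, cap)
    d2 = np.minimum(d2, cap)
    return Scan.from_arrays(scan_id, zen, az, d1, i1, d2, i2,
                            instrument=instrument, label=None,
                            metadata={"scene": "room",
                                      "config": dataclasses.asdict(config)})


def _trunk_hit_distance(rng_trunks, zen, az, config: ForestSceneConfig) -> np.ndarray:
    """Nearest positive ray-cylinder intersection per pulse (inf if none)."""
    n = zen.size
    if config.trunk_count <= 0:
        return np.full(n, np.inf)
    r = config.stand_radius * np.sqrt(rng_trunks.random(config.trunk_count))
    theta = rng_trunks.uniform(0, 2 * np.pi, config.trunk_count)
    cx, cy = r * np.cos(theta), r * np.sin(theta)
    # keep trunks clear of the sensor
    keep = (cx ** 2 + cy ** 2) > (config.trunk_radius + 0.5) ** 2
    cx, cy = cx[keep], cy[keep]

    zr = np.deg2rad(zen)
    ar = np.deg2rad(az)
    dx = (np.sin(zr) * np.cos(ar))[:, None]
    dy = (np.sin(zr) * np.sin(ar))[:, None]
    dz = np.cos(zr)[:, None]
    hh = dx ** 2 + dy ** 2  # squared horizontal direction component
    b = -(dx * cx[None, :] + dy * cy[None, :])
    c = (cx ** 2 + cy ** 2)[None, :] - config.trunk_radius ** 2
    disc = b ** 2 - hh * c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((disc >= 0) & (hh > 1e-12),
                     (-b - np.sqrt(np.maximum(disc, 0.0))) / hh, np.inf)
    t = np.where(t > 1e-6, t, np.inf)
    # trunks exist from the ground up to the canopy base
    zhit = t * dz
    t = np.where((zhit >= -config.ground_depth - 1e-9)
                 & (zhit <= config.canopy_base_height + 1e-9), t, np.inf)
    return t.min(axis=1)


def generate_forest_scan(pattern: ScanPattern = ScanPattern(),
                         config: ForestSceneConfig = ForestSceneConfig(),
                         scan_id="forest", seed: Optional[int] = None,
                         instrument: Optional[InstrumentSpec] = None) -> Scan:
    """Stochastic ray-cast of a forest stand.

    Per pulse: a skyward pulse (zenith < 90°) escapes through a canopy gap
    with probability ``canopy_gap_prob``; otherwise the first interception
    is the nearest of (a) a trunk cylinder, (b) an exponential free path
    through the understory while the ray is below the canopy base, (c) the
    canopy base surface (skyward rays), or (d) the ground plane (downward
    rays).  Interceptions beyond ``max_range_clip`` are recorded as
    no-returns.  A returned pulse yields a second return with probability
    ``second_return_prob``, placed a short free path beyond the first.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    zen, az = pattern.grid()
    n = zen.size
    zr = np.deg2rad(zen)
    cosz = np.cos(zr)

    # path length below the canopy base along each ray (inf for horizontal)
    with np.errstate(divide="ignore"):
        to_canopy = np.where(cosz > 1e-9, config.canopy_base_height / cosz, np.inf)
        to_ground = np.where(cosz < -1e-9, -config.ground_depth / cosz, np.inf)
    layer_len = np.minimum(to_canopy, to_ground)

    trunk_t = _trunk_hit_distance(rng, zen, az, config)
    under_t = np.where(
        config.understory_density > 0,
        rng.exponential(1.0 / max(config.understory_density, 1e-12), size=n),
        np.inf)
    under_t = np.where(under_t <= layer_len, under_t, np.inf)

    # canopy itself: entering rays are intercepted a short exponential depth
    # past the base (fragmented but dense foliage)
    canopy_depth = rng.exponential(1.0, size=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        canopy_t = np.where(np.isfinite(to_canopy),
                            to_canopy + canopy_depth / np.maximum(cosz, 1e-9), np.inf)
    ground_t = to_ground

    first = np.minimum.reduce([trunk_t, under_t, canopy_t, ground_t])
    escaped = (zen < 90.0) & (rng.random(n) < config.canopy_gap_prob)
    no_return = escaped | (first > config.max_range_clip) | ~np.isfinite(first)

    d1 = np.where(no_return, np.nan, first)
    d1 = _noisy_positive(rng, d1, config.range_noise_sd_m)
    d1 = np.minimum(d1, config.max_range_clip)
    i1 = np.where(no_return, np.nan,
                  _intensities(rng, n, config.reflectance_mean, config.reflectance_sd))

    second = ~no_return & (rng.random(n) < config.second_return_prob)
    gap_behind = rng.exponential(1.5, size=n)
    d2 = np.where(second, d1 + 0.1 + gap_behind, np.nan)
    beyond = second & (d2 > config.max_range_clip)
    d2[beyond] = np.nan
    second &= ~beyond
    i2 = np.where(second,
                  _intensities(rng, n, config.reflectance_mean * 0.7,
                               config.reflectance_sd), np.nan)

    instrument = instrument or InstrumentSpec()
    return Scan.from_arrays(scan_id, zen, az, d1, i1, d2, i2,
                            instrument=instrument, label=None,
                            metadata={"scene": "forest",
                                      "config": dataclasses.asdict(config)})


def _jitter(rng, value, rel):
    return value * (1.0 + rng.uniform(-rel, rel))


def _jittered_room(rng, base: RoomSceneConfig) -> RoomSceneConfig:
    return dataclasses.replace(
        base,
        half_width_x=_jitter(rng, base.half_width_x, 0.2),
        half_width_y=_jitter(rng, base.half_width_y, 0.2),
        ceiling_height=_jitter(rng, base.ceiling_height, 0.15),
        reflectance_mean=float(np.clip(_jitter(rng, base.reflectance_mean, 0.08),
                                       0.05, 0.95)),
        second_return_prob=float(np.clip(_jitter(rng, base.second_return_prob, 0.2),
                                         0.0, 1.0)),
    )


def _jittered_forest(rng, base: ForestSceneConfig) -> ForestSceneConfig:
    return dataclasses.replace(
        base,
        canopy_base_height=_jitter(rng, base.canopy_base_height, 0.1),
        canopy_top_height=_jitter(rng, base.canopy_top_height, 0.1),
        canopy_gap_prob=float(np.clip(_jitter(rng, base.canopy_gap_prob, 0.2),
                                      0.02, 0.9)),
        understory_density=_jitter(rng, base.understory_density, 0.2),
        second_return_prob=float(np.clip(_jitter(rng, base.second_return_prob, 0.1),
                                         0.05, 0.9)),
        reflectance_mean=float(np.clip(_jitter(rng, base.reflectance_mean, 0.1),
                                       0.05, 0.95)),
    )


def generate_labeled_dataset(n_class0: int, n_class1: int,
                             class0_config: RoomSceneConfig = RoomSceneConfig(),
                             class1_config: ForestSceneConfig = ForestSceneConfig(),
                             pattern: ScanPattern = ScanPattern(),
                             base_seed: int = 0,
                             jitter: bool = True) -> List[Scan]:
    """Generate a labeled mixed dataset of room (label 0) and forest (label 1) scans.

    Per-scan seeds are spawned deterministically from ``base_seed``; scene
    configs receive mild per-scan jitter (canopy height ±10%, gap
    probability ±20%, room dimensions ±20%, ...) to create within-class
    variance.  Two calls with the same arguments yield identical datasets.
    """
    if n_class0 < 1 or n_class1 < 1:
        raise ValidationError("both classes need at least one scan")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_class0 + n_class1)
    scans: List[Scan] = []
    for i in range(n_class0):
        rng = np.random.default_rng(children[i])
        cfg = _jittered_room(rng, class0_config) if jitter else class0_config
        scan = generate_room_scan(pattern, cfg, scan_id=f"room_{i:03d}",
                                  seed=int(rng.integers(0, 2 ** 31)))
        scan.label = 0
        scans.append(scan)
    for j in range(n_class1):
        rng = np.random.default_rng(children[n_class0 + j])
        cfg = _jittered_forest(rng, class1_config) if jitter else class1_config
        scan = generate_forest_scan(pattern, cfg, scan_id=f"forest_{j:03d}",
                                    seed=int(rng.integers(0, 2 ** 31)))
        scan.label = 1
        scans.append(scan)
    return scans
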