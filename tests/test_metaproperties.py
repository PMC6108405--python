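import math

import numpy as np
import pytest
from scipy.spatial import Delaunay

from tlsmeta import (
    MetapropertyConfig,
    Scan,
    extract_all,
    extract_table,
    spherical_to_cartesian,
)
from tlsmeta.errors import NotComputableError, ValidationError
from tlsmeta.metaproperties import (
    first_second_ratio,
    mean_distance,
    mean_intensity,
    no_return_ratio,
    optical_plane_area,
    polygon_area,
    rugosity,
)

from conftest import make_pulse, random_scan


def scan_of(pulses, scan_id="s"):
    return Scan(scan_id, pulses)


# ---------------------------------------------------------------- oracles

def brute_force_metrics(scan, config=MetapropertyConfig()):
    """Independent naive implementations over PulseRecord objects."""
    out = {}
    lo, hi = config.pulse_band
    firsts = [p.first_return for p in scan.pulses
              if lo <= p.zenith_deg <= hi and p.first_return]
    if firsts:
        out["mean_distance"] = sum(r.distance for r in firsts) / len(firsts)
        out["mean_intensity"] = sum(r.intensity for r in firsts) / len(firsts)
        n2 = sum(1 for p in scan.pulses
                 if lo <= p.zenith_deg <= hi and p.n_returns == 2)
        out["first_second_ratio"] = len(firsts) / n2 if n2 else math.inf
    glo, ghi = config.gap_band
    band = [p for p in scan.pulses if glo <= p.zenith_deg <= ghi]
    if band:
        out["no_return_ratio"] = sum(1 for p in band if p.n_returns == 0) / len(band)
    return out


# ------------------------------------------------------- pulse metaproperties

class TestPulseMetaproperties:
    def test_mean_distance_simple_average(self):
        scan = scan_of([make_pulse("a", 40, 0, [(4, 0.2)]),
                        make_pulse("b", 50, 0, [(6, 0.4)])])
        assert mean_distance(scan) == pytest.approx(5.0)
        assert mean_intensity(scan) == pytest.approx(0.3)

    def test_no_return_pulses_do_not_contribute(self):
        pulses = [make_pulse("a", 40, 0, [(4, 0.2)]),
                  make_pulse("b", 50, 0, [(6, 0.4)])]
        pulses += [make_pulse(f"n{i}", 45, i, []) for i in range(10)]
        assert mean_distance(scan_of(pulses)) == pytest.approx(5.0)

    def test_below_optical_plane_excluded(self):
        scan = scan_of([make_pulse("a", 80, 0, [(4, 0.2)]),
                        make_pulse("b", 120, 0, [(100 / 3, 0.9)])])
        assert mean_distance(scan) == pytest.approx(4.0)

    def test_first_second_ratio_counts(self):
        pulses = [make_pulse(f"a{i}", 45, i, [(5, 0.5), (6, 0.4)]) for i in range(25)]
        pulses += [make_pulse(f"b{i}", 45, 180 + i * 0.1, [(5, 0.5)]) for i in range(75)]
        assert first_second_ratio(scan_of(pulses)) == pytest.approx(4.0)

    def test_zero_second_returns_gives_infinite_sentinel(self):
        pulses = [make_pulse(f"a{i}", 45, i, [(5, 0.5)]) for i in range(50)]
        assert math.isinf(first_second_ratio(scan_of(pulses)))
        vec = extract_all(scan_of(pulses))
        assert "first_second_ratio" in vec.flags

    def test_no_first_returns_raises(self):
        scan = scan_of([make_pulse("a", 45, 0, [])])
        for fn in (mean_distance, mean_intensity, first_second_ratio):
            with pytest.raises(NotComputableError):
                fn(scan)


class TestNoReturnRatio:
    def test_fraction_in_gap_band(self):
        pulses = [make_pulse(f"g{i}", 32, i, []) for i in range(3)]
        pulses += [make_pulse(f"r{i}", 33, 90 + i, [(5, 0.5)]) for i in range(7)]
        assert no_return_ratio(scan_of(pulses)) == pytest.approx(0.3)

    def test_zero_when_every_band_pulse_returns(self):
        pulses = [make_pulse(f"r{i}", 33, i, [(5, 0.5)]) for i in range(10)]
        assert no_return_ratio(scan_of(pulses)) == 0.0

    def test_empty_band_raises(self):
        scan = scan_of([make_pulse("a", 60, 0, [(5, 0.5)])])
        with pytest.raises(NotComputableError):
            no_return_ratio(scan)

    def test_adding_returned_pulse_never_increases_ratio(self, rng):
        pulses = [make_pulse(f"g{i}", 32, i, [] if rng.random() < 0.4 else [(5, 0.5)])
                  for i in range(30)]
        before = no_return_ratio(scan_of(pulses))
        pulses.append(make_pulse("extra", 34, 300, [(6, 0.5)]))
        assert no_return_ratio(scan_of(pulses)) <= before


# ------------------------------------------------------------- optical plane

class TestOpticalPlaneArea:
    def test_unit_diamond(self):
        pulses = [make_pulse(f"p{a}", 90, a, [(1.0, 0.5)]) for a in (0, 90, 180, 270)]
        assert optical_plane_area(scan_of(pulses)) == pytest.approx(2.0)

    def test_regular_polygon_closed_form(self):
        n, d = 360, 10.0
        pulses = [make_pulse(f"p{i}", 90, i * (360 / n), [(d, 0.5)]) for i in range(n)]
        expected = 0.5 * n * d * d * math.sin(2 * math.pi / n)
        assert optical_plane_area(scan_of(pulses)) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(math.pi * d * d, rel=1e-4)

    def test_two_vertices_not_computable(self):
        pulses = [make_pulse("a", 90, 0, [(1, 0.5)]), make_pulse("b", 90, 90, [(1, 0.5)])]
        with pytest.raises(NotComputableError):
            optical_plane_area(scan_of(pulses))

    def test_no_return_plane_pulses_skipped(self):
        pulses = [make_pulse(f"p{a}", 90, a, [(1.0, 0.5)]) for a in (0, 90, 180, 270)]
        pulses.append(make_pulse("gap", 90, 45, []))
        assert optical_plane_area(scan_of(pulses)) == pytest.approx(2.0)

    def test_matches_shapely_on_star_shaped_scene(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon
        az = np.sort(rng.uniform(0, 360, 40))
        d = rng.uniform(2, 20, 40)
        pulses = [make_pulse(f"p{i}", 90, a, [(di, 0.5)])
                  for i, (a, di) in enumerate(zip(az, d))]
        got = optical_plane_area(scan_of(pulses))
        xy = [(di * math.cos(math.radians(a)), di * math.sin(math.radians(a)))
              for a, di in zip(az, d)]
        assert got == pytest.approx(Polygon(xy).area, abs=1e-9)

    def test_rotation_invariance_and_quadratic_scaling(self, rng):
        az = np.sort(rng.uniform(0, 360, 30))
        d = rng.uniform(1, 10, 30)  # keeps 3x-scaled distances within range

        def area(azimuths, dists):
            pulses = [make_pulse(f"p{i}", 90, a % 360, [(di, 0.5)])
                      for i, (a, di) in enumerate(zip(azimuths, dists))]
            return optical_plane_area(scan_of(pulses))

        base = area(az, d)
        rotated = area(az + 73.0, d)
        assert rotated == pytest.approx(base, rel=1e-9)
        assert area(az, 3.0 * d) == pytest.approx(9.0 * base, rel=1e-9)


# ------------------------------------------------------------------ rugosity

def _grid_scan(zfun, n=5, spacing=1.0, height=3.0):
    """Near-square grid of first returns in the 0-30 deg band.

    Grid positions carry a small deterministic jitter so no four points are
    cocircular: the Delaunay triangulation is then unique, which matters for
    tests that compare rugosity across two builds of the same surface.
    """
    pulses = []
    k = 0
    for i in range(n):
        for j in range(n):
            x = (i - (n - 1) / 2) * spacing * 0.2 + 0.003 * math.sin(7.3 * i + 1.7 * j)
            y = (j - (n - 1) / 2) * spacing * 0.2 + 0.003 * math.cos(3.1 * i - 5.9 * j)
            z = zfun(x, y)
            d = math.sqrt(x * x + y * y + z * z)
            zen = math.degrees(math.acos(z / d))
            azm = math.degrees(math.atan2(y, x)) % 360
            pulses.append(make_pulse(f"g{k}", zen, azm, [(d, 0.5)]))
            k += 1
    return scan_of(pulses)


class TestRugosity:
    def test_flat_grid_is_one(self):
        scan = _grid_scan(lambda x, y: 3.0)
        assert rugosity(scan) == pytest.approx(1.0, abs=1e-9)

    def test_tilted_plane_slope_factor(self):
        # plane tilted 60 deg from horizontal: 3-D area = footprint / cos 60 = 2x
        scan = _grid_scan(lambda x, y: 3.0 + math.sqrt(3) * x)
        assert rugosity(scan) == pytest.approx(2.0, abs=1e-6)

    def test_invariant_to_constant_z_offset(self):
        rng = np.random.default_rng(3)
        heights = {}

        def zf(x, y):
            return heights.setdefault((round(x, 6), round(y, 6)),
                                      3.0 + rng.normal(0, 0.1))

        r1 = rugosity(_grid_scan(zf))
        r2 = rugosity(_grid_scan(lambda x, y: zf(x, y) + 5.0))
        assert r2 == pytest.approx(r1, rel=1e-9)
        assert r1 >= 1.0 - 1e-9

    def test_matches_independent_triangle_sum(self, rng):
        scan = _grid_scan(lambda x, y: 3.0 + 0.3 * math.sin(7 * x) * math.cos(5 * y))
        got = rugosity(scan)
        m = scan.band_mask(0, 30) & scan.has_return
        x, y, z = spherical_to_cartesian(scan.r1_distance[m], scan.zenith_deg[m],
                                         scan.azimuth_deg[m])
        tri = Delaunay(np.column_stack([x, y]))
        area3d = 0.0
        area2d = 0.0
        for a, b, c in tri.simplices:
            p0 = np.array([x[a], y[a], z[a]])
            p1 = np.array([x[b], y[b], z[b]])
            p2 = np.array([x[c], y[c], z[c]])
            area3d += 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0))
            u, v = p1[:2] - p0[:2], p2[:2] - p0[:2]
            area2d += 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        assert got == pytest.approx(area3d / area2d, abs=1e-9)

    def test_collinear_points_not_computable(self):
        pulses = [make_pulse(f"c{i}", 10 + i, 0, [(3.0, 0.5)]) for i in range(5)]
        with pytest.raises(NotComputableError):
            rugosity(scan_of(pulses))


# ---------------------------------------------------------- orchestration

class TestExtraction:
    def test_missing_opa_is_flagged_not_fatal(self):
        pulses = [make_pulse(f"p{i}", 40 + i, i * 10, [(5, 0.5), (6, 0.4)])
                  for i in range(20)]
        pulses += [make_pulse(f"g{i}", 32, i, []) for i in range(5)]
        pulses += [make_pulse(f"r{i}{j}", 5 + i * 5, j * 72, [(3, 0.5)])
                   for i in range(5) for j in range(5)]
        vec = extract_all(Scan("s", pulses))
        assert "opa" in vec.flags and math.isnan(vec.opa)
        assert not math.isnan(vec.mean_distance)
        assert not math.isnan(vec.rugosity)

    def test_empty_scan_rejected(self):
        with pytest.raises(ValidationError):
            extract_all(Scan("s", []))

    def test_batch_table_preserves_order(self, labeled_dataset):
        table = extract_table(labeled_dataset)
        assert list(table["scan_id"]) == [s.scan_id for s in labeled_dataset]
        assert list(table["label"]) == [s.label for s in labeled_dataset]

    def test_all_metrics_match_brute_force_on_random_scans(self):
        rng = np.random.default_rng(777)
        checked = 0
        for _ in range(100):
            scan = random_scan(rng, n_pulses=80)
            oracle = brute_force_metrics(scan)
            for name, expected in oracle.items():
                fn = {"mean_distance": mean_distance,
                      "mean_intensity": mean_intensity,
                      "first_second_ratio": first_second_ratio,
                      "no_return_ratio": no_return_ratio}[name]
                try:
                    got = fn(scan)
                except NotComputableError:
                    continue
                if math.isinf(expected):
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked > 300

    def test_bounded_by_contributing_values(self, rng):
        scan = random_scan(rng, n_pulses=120)
        m = scan.band_mask(0, 90) & scan.has_return
        if m.any():
            d = mean_distance(scan)
            assert scan.r1_distance[m].min() <= d <= scan.r1_distance[m].max()
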