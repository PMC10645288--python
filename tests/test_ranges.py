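"""Range polygons, range/niche filling, threat maps, effort adjustment."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from invasionfill.niche import (NBINS, analogue_cells, niche_cells,
                                occurrence_density, potential_range)
from invasionfill.ranges import (RangePolygonSet, ThreatMap, covered_mask,
                                 effort_adjust, median_range_filling,
                                 niche_filling, range_filling, range_polygons,
                                 threat_map)
from invasionfill.synthetic_world import OccurrenceSet


def points_occ(grid, cells, species="sp", status="naturalised"):
    lon, lat = grid.cell_centre(np.array([c[0] for c in cells]),
                                np.array([c[1] for c in cells]))
    return OccurrenceSet(species, pd.DataFrame(
        {"lon": lon, "lat": lat, "status": status}))


def manual_polyset(geom, realm=2):
    return RangePolygonSet("sp", realm, {1: geom}, geom, 0.0)


class TestRangePolygons:
    def test_triangle_hull_contains_points(self, world):
        occ = points_occ(world, [(35, 40), (40, 45), (36, 48)])
        poly = range_polygons(occ, world, 2)
        for _, p in occ.records.iterrows():
            assert poly.union.buffer(1e-9).contains(shapely.Point(p.lon, p.lat))

    def test_hulls_never_bridge_admin_units(self, world):
        # two clusters in different admin units of realm 2
        occ = points_occ(world, [(5, 35), (6, 36), (5, 37), (50, 55), (52, 56), (51, 57)])
        poly = range_polygons(occ, world, 2)
        assert len(poly.hulls) >= 2
        all_hull = shapely.MultiPoint(
            [shapely.Point(xy) for xy in occ.records[["lon", "lat"]].to_numpy()]
        ).convex_hull
        assert poly.union.area < all_hull.area / 2

    def test_single_point_buffered_disc(self, world):
        occ = points_occ(world, [(40, 40)])
        poly = range_polygons(occ, world, 2)
        lon, lat = world.cell_centre(np.array([40]), np.array([40]))
        disc = shapely.Point(lon[0], lat[0]).buffer(world.cell_size / 2)
        assert poly.union.area == pytest.approx(disc.area, rel=0.01)

    def test_no_naturalised_errors(self, world):
        occ = points_occ(world, [(40, 40)], status="native")
        with pytest.raises(ValueError):
            range_polygons(occ, world, 2)


class TestRangeFilling:
    def potential(self, world, cells):
        from invasionfill.niche import PotentialRange
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        area = float(world.cell_area_km2()[rows, cols].sum())
        return PotentialRange(rows=rows, cols=cols, area_km2=area, realm=2)

    def test_full_coverage_is_one(self, world):
        cells = [(r, c) for r in range(30, 35) for c in range(40, 45)]
        pot = self.potential(world, cells)
        lo = world.cell_centre(np.array([29]), np.array([39]))
        hi = world.cell_centre(np.array([36]), np.array([46]))
        big = box(float(lo[0][0]), float(lo[1][0]), float(hi[0][0]), float(hi[1][0]))
        assert range_filling(pot, manual_polyset(big), world) == 1.0

    def test_disjoint_is_zero(self, world):
        pot = self.potential(world, [(30, 40), (31, 41)])
        far = box(0.1, 0.1, 0.3, 0.3)
        assert range_filling(pot, manual_polyset(far), world) == 0.0

    def test_equal_area_half_coverage(self, world):
        """Two columns at identical latitudes; cover one: area-weighted 0.5."""
        cells = [(r, 40) for r in range(20, 40)] + [(r, 42) for r in range(20, 40)]
        pot = self.potential(world, cells)
        lon_lo, lat_lo = world.cell_centre(np.array([19]), np.array([39]))
        lon_hi, lat_hi = world.cell_centre(np.array([40]), np.array([41]))
        col_box = box(lon_lo[0], lat_lo[0], lon_hi[0] - world.cell_size / 2, lat_hi[0])
        assert range_filling(pot, manual_polyset(col_box), world) == pytest.approx(0.5)

    def test_monotone_in_occurrences(self, world, space, occurrences):
        pot = potential_range(occurrences, space, world)
        rec = occurrences.records
        nat = rec[rec["status"] == "naturalised"]
        sub = OccurrenceSet("sp", pd.concat([rec[rec["status"] == "native"],
                                             nat.iloc[:10]]))
        f_sub = range_filling(pot, range_polygons(sub, world, 2), world)
        f_all = range_filling(pot, range_polygons(occurrences, world, 2), world)
        assert f_all >= f_sub

    def test_zero_potential_errors(self, world):
        from invasionfill.niche import PotentialRange
        pot = PotentialRange(rows=np.array([], int), cols=np.array([], int),
                             area_km2=0.0, realm=2)
        with pytest.raises(ValueError):
            range_filling(pot, manual_polyset(box(0, 0, 1, 1)), world)


class TestNicheFilling:
    def test_extremes_and_fraction(self, world, space, occurrences):
        d = occurrence_density(occurrences, space, world, realm="native")
        cells = niche_cells(d)
        full = niche_filling(cells, occurrences, space, world)
        assert 0.0 <= full <= 1.0
        none = OccurrenceSet("sp", occurrences.records[
            occurrences.records["status"] == "native"])
        assert niche_filling(cells, none, space, world) == 0.0

    def test_simple_fraction(self, world, space):
        cells = np.zeros((NBINS, NBINS), bool)
        an = analogue_cells(space)
        ai, aj = np.nonzero(an)
        cells[ai[:20], aj[:20]] = True
        # occupy 5 of the 20 cells via cell-centre occurrences from realm 2
        rr, cc = world.realm_cells(2)
        clim = world.climate[:, rr, cc].T
        ix, iy = space.bin_of(space.scores(clim))
        want = {(ai[k], aj[k]) for k in range(5)}
        sel = [i for i in range(len(rr)) if (ix[i], iy[i]) in want]
        lon, lat = world.cell_centre(rr[sel], cc[sel])
        occ = OccurrenceSet("sp", pd.DataFrame(
            {"lon": lon, "lat": lat, "status": "naturalised"}))
        got = niche_filling(cells, occ, space, world)
        assert got == pytest.approx(len({(ix[i], iy[i]) for i in sel}) / 20)


class TestThreatMap:
    def make_record(self, world, pot_cells, poly_geom):
        from invasionfill.niche import PotentialRange
        rows = np.array([c[0] for c in pot_cells])
        cols = np.array([c[1] for c in pot_cells])
        pot = PotentialRange(rows=rows, cols=cols, area_km2=1.0, realm=2)
        return pot, (manual_polyset(poly_geom) if poly_geom is not None else None)

    def test_fully_filled_species_contributes_zero(self, world):
        cells = [(30, 40), (30, 41)]
        big = box(6.5, 4.9, 7.1, 5.2)
        pot, poly = self.make_record(world, cells, big)
        assert covered_mask(poly, world)[30, 40]
        tm = threat_map([(pot, poly)], world)
        assert not tm.counts.any()

    def test_two_identical_species_stack(self, world):
        cells = [(30, 40), (31, 41)]
        recs = [self.make_record(world, cells, None) for _ in range(2)]
        tm = threat_map(recs, world)
        assert tm.counts[30, 40] == 2 and tm.counts[31, 41] == 2
        assert tm.counts.sum() == 4

    def test_matches_brute_force(self, world):
        rng = np.random.default_rng(3)
        recs = []
        for s in range(3):
            cells = sorted({(int(r), int(c)) for r, c in
                            zip(rng.integers(25, 45, 15), rng.integers(35, 55, 15))})
            lon, lat = world.cell_centre(np.array([cells[0][0]]), np.array([cells[0][1]]))
            geom = shapely.Point(lon[0], lat[0]).buffer(0.4)
            recs.append(self.make_record(world, cells, geom))
        tm = threat_map(recs, world)
        # oracle: per-cell loop
        expected = np.zeros(world.shape, dtype=int)
        for pot, poly in recs:
            cov = covered_mask(poly, world)
            for r, c in zip(pot.rows, pot.cols):
                if not cov[r, c]:
                    expected[r, c] += 1
        assert np.array_equal(tm.counts, expected)

    def test_conservation(self, world):
        rng = np.random.default_rng(4)
        recs = []
        total = 0
        for s in range(3):
            cells = sorted({(int(r), int(c)) for r, c in
                            zip(rng.integers(25, 45, 10), rng.integers(35, 55, 10))})
            recs.append(self.make_record(world, cells, None))
            total += len(cells)
        assert threat_map(recs, world).counts.sum() == total


class TestEffortAdjust:
    def test_reciprocal_scaling(self):
        tm = ThreatMap(counts=np.full((5, 5), 10))
        out = effort_adjust(tm, np.full((5, 5), 0.5))
        assert (out.adjusted == 20).all()

    def test_floor_caps_inflation(self):
        tm = ThreatMap(counts=np.full((3, 3), 10))
        out = effort_adjust(tm, np.zeros((3, 3)))
        assert (out.adjusted == 100_000).all()

    def test_identity_at_full_detection(self):
        tm = ThreatMap(counts=np.arange(9).reshape(3, 3))
        out = effort_adjust(tm, np.ones((3, 3)))
        assert np.array_equal(out.adjusted, tm.counts)

    def test_never_decreases(self):
        rng = np.random.default_rng(0)
        tm = ThreatMap(counts=rng.integers(0, 5, (10, 10)))
        out = effort_adjust(tm, rng.random((10, 10)))
        assert (out.adjusted >= tm.counts).all()

    def test_nearest_neighbour_resample(self):
        tm = ThreatMap(counts=np.full((4, 4), 8))
        det = np.array([[0.5, 1.0], [1.0, 0.25]])
        out = effort_adjust(tm, det)
        assert out.adjusted[0, 0] == 16 and out.adjusted[3, 3] == 32

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            effort_adjust(ThreatMap(counts=np.ones((2, 2))), np.full((2, 2), 1.5))


def test_median_range_filling():
    df = pd.DataFrame({"taxon": ["mammal"] * 3 + ["bird"],
                       "filling": [0.02, 0.04, 0.30, 0.5]})
    assert median_range_filling(df, taxon="mammal") == pytest.approx(4.0)
    assert median_range_filling(df, taxon="mammal", percent=False) == pytest.approx(0.04)
    with pytest.raises(ValueError):
        median_range_filling(df, taxon="fish")
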