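"""Climate space, kernel densities, niche cells, projection, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from invasionfill.grids import ClimateGrid
from invasionfill.niche import (NBINS, ClimateSpace, DensityGrid,
                                analogue_cells, build_climate_space,
                                crossvalidate, niche_cells, occurrence_density,
                                potential_range, project_range, tss)
from invasionfill.synthetic_world import (OccurrenceSet, SpeciesTruth,
                                          WorldConfig, make_species,
                                          make_world, true_suitable_mask)


class TestClimateSpace:
    def test_pooled_scaling_zero_mean_unit_sd(self, world, space):
        pooled = np.vstack([world.realm_climate(1), world.realm_climate(2)])
        scaled = space.scale_climate(pooled)
        assert np.allclose(scaled.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(scaled.std(axis=0), 1.0, atol=1e-9)

    def test_pooled_scores_inside_bounds(self, world, space):
        pooled = np.vstack([world.realm_climate(1), world.realm_climate(2)])
        s = space.scores(pooled)
        ix, iy = space.bin_of(s)
        assert (ix >= 0).all() and (iy >= 0).all()
        assert (ix < NBINS).all() and (iy < NBINS).all()

    def test_every_realm_cell_maps_to_one_bin(self, space):
        assert space.avail_native.sum() + space.avail_intro.sum() > 0
        # counts are integers and conserve the number of cells
        assert space.avail_native.sum() == int(space.avail_native.sum())

    def test_perfectly_correlated_variables_single_axis(self):
        """All three variables affine in one field: axis 1 carries ~all variance."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 30))
        climate = np.stack([base * 5, base * 2 + 10, base * 100 + 1000])
        land = np.ones((30, 30), bool)
        realm = np.where(np.arange(30)[None, :] < 15, 1, 2) * land
        grid = ClimateGrid(climate=climate, land=land, realm=realm,
                           admin=realm, cell_size=0.5)
        space = build_climate_space(grid, 1, 2)
        assert space.explained_variance_ratio_[0] > 0.99

    def test_constant_variable_errors(self):
        climate = np.stack([np.random.default_rng(0).normal(size=(25, 25)),
                            np.full((25, 25), 7.0), np.full((25, 25), 500.0)])
        land = np.ones((25, 25), bool)
        realm = np.where(np.arange(25)[None, :] < 12, 1, 2) * land
        grid = ClimateGrid(climate=climate, land=land, realm=realm,
                           admin=realm, cell_size=0.5)
        with pytest.raises(ValueError):
            build_climate_space(grid, 1, 2)


class TestOccurrenceDensity:
    def test_single_occurrence_mode_at_its_cell(self, world, space):
        rr, cc = world.realm_cells(1)
        # pick a realm cell whose climate is analogue (present in both realms)
        clim_all = world.climate[:, rr, cc].T
        ia, ja = space.bin_of(space.scores(clim_all))
        k = int(np.nonzero(analogue_cells(space)[ia, ja])[0][0])
        lon, lat = world.cell_centre(rr[k], cc[k])
        d = occurrence_density(np.array([[lon, lat]]), space, world,
                               realm="native", min_points=1)
        mode = np.unravel_index(d.corrected.argmax(), d.corrected.shape)
        clim = world.climate_at(np.array([lon]), np.array([lat]))
        ix, iy = space.bin_of(space.scores(clim))
        assert abs(mode[0] - ix[0]) <= 1 and abs(mode[1] - iy[0]) <= 1

    def test_threshold_rule_holds(self, world, space, occurrences):
        d = occurrence_density(occurrences, space, world, realm="native")
        nz = d.corrected[d.corrected > 0]
        assert (nz >= d.corrected.max() / 1000).all()

    def test_zero_where_unavailable(self, world, space, occurrences):
        d = occurrence_density(occurrences, space, world, realm="native")
        assert not d.corrected[space.avail_native == 0].any()

    def test_duplication_invariance(self, world, space, occurrences):
        rec = occurrences.records
        doubled = OccurrenceSet(occurrences.species,
                                pd.concat([rec, rec], ignore_index=True))
        a = occurrence_density(occurrences, space, world, realm="native")
        b = occurrence_density(doubled, space, world, realm="native")
        assert np.allclose(a.corrected, b.corrected)

    def test_too_few_points_errors(self, world, space):
        rr, cc = world.realm_cells(1)
        lon, lat = world.cell_centre(rr[:3], cc[:3])
        with pytest.raises(ValueError):
            occurrence_density(np.column_stack([lon, lat]), space, world)

    def test_uniform_occurrences_flat_corrected_density(self):
        """Occurrences at every realm cell: corrected density ~constant over
        the well-available interior of the occupied climate region."""
        rng = np.random.default_rng(4)
        r1 = rng.normal(size=(40, 40)) * 0.01
        climate = np.stack([np.linspace(-10, 10, 40)[:, None].repeat(40, 1) + r1,
                            np.linspace(0, 20, 40)[:, None].repeat(40, 1)
                            + rng.normal(size=(40, 40)) * 0.5,
                            np.full((40, 40), 800.0) + rng.normal(size=(40, 40))])
        land = np.ones((40, 40), bool)
        realm = np.where(np.arange(40)[None, :] < 20, 1, 2) * land
        grid = ClimateGrid(climate=climate, land=land, realm=realm,
                           admin=realm, cell_size=0.5)
        space = build_climate_space(grid, 1, 2)
        rr, cc = grid.realm_cells(1)
        lon, lat = grid.cell_centre(rr, cc)
        d = occurrence_density(np.column_stack([lon, lat]), space, grid,
                               realm="native")
        interior = d.availability > np.percentile(d.availability[d.corrected > 0], 60)
        vals = d.corrected[(d.corrected > 0) & interior]
        assert vals.std() / vals.mean() < 0.2


def manual_density(shape_vals):
    d = np.zeros((NBINS, NBINS))
    for (i, j), v in shape_vals.items():
        d[i, j] = v
    return DensityGrid(raw=d, availability=np.ones_like(d), corrected=d,
                       bandwidth=0.1, n_points=10)


class TestNicheCells:
    def test_all_mass_one_cell(self):
        d = manual_density({(3, 4): 5.0})
        cells = niche_cells(d, core_quantile=0.7)
        assert cells.sum() == 1 and cells[3, 4]

    def test_nesting(self, world, space, occurrences):
        d = occurrence_density(occurrences, space, world, realm="native")
        core = niche_cells(d, 0.7)
        full = niche_cells(d, 1.0)
        assert (core <= full).all() and core.sum() < full.sum()

    def test_four_equal_cells_ceiling(self):
        d = manual_density({(0, 0): 1.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 1.0})
        assert niche_cells(d, 0.7).sum() == 3

    def test_empty_density_errors(self):
        with pytest.raises(ValueError):
            niche_cells(manual_density({}))


class TestAnalogue:
    def make_space(self, avail_n, avail_i):
        return ClimateSpace(
            mean_=np.zeros(3), sd_=np.ones(3), components_=np.eye(2, 3),
            explained_variance_ratio_=np.array([0.6, 0.4]),
            bounds=np.array([[0.0, 1.0], [0.0, 1.0]]),
            native_realm=1, introduced_realm=2,
            avail_native=avail_n, avail_intro=avail_i)

    def test_identical_realms(self):
        a = np.zeros((NBINS, NBINS))
        a[10:20, 10:20] = 1
        sp = self.make_space(a, a.copy())
        assert np.array_equal(analogue_cells(sp), a > 0)

    def test_disjoint_climates_empty(self):
        a = np.zeros((NBINS, NBINS)); a[:10] = 1
        b = np.zeros((NBINS, NBINS)); b[50:] = 1
        assert not analogue_cells(self.make_space(a, b)).any()

    def test_one_dimensional_overlap(self):
        a = np.zeros((NBINS, NBINS)); a[10:61] = 1
        b = np.zeros((NBINS, NBINS)); b[40:91] = 1
        got = analogue_cells(self.make_space(a, b))
        assert set(np.unique(np.nonzero(got)[0])) == set(range(40, 61))


class TestProjection:
    def test_empty_set_empty_range(self, world, space):
        pot = project_range(np.zeros((NBINS, NBINS), bool), space, world, 2)
        assert pot.n_cells == 0 and pot.area_km2 == 0.0

    def test_full_analogue_set_covers_analogue_cells(self, world, space):
        pot = project_range(analogue_cells(space), space, world, 2)
        rr, cc = world.realm_cells(2)
        clim = world.climate[:, rr, cc].T
        ix, iy = space.bin_of(space.scores(clim))
        expected = analogue_cells(space)[ix, iy]
        assert pot.n_cells == int(expected.sum())

    def test_projection_round_trip(self, world, space, occurrences):
        d = occurrence_density(occurrences, space, world, realm="native")
        cells = niche_cells(d) & analogue_cells(space)
        pot = project_range(cells, space, world, 2)
        clim = world.climate[:, pot.rows, pot.cols].T
        ix, iy = space.bin_of(space.scores(clim))
        assert cells[ix, iy].all()

    def test_area_is_cos_weighted(self, world, space):
        full = np.ones((NBINS, NBINS), bool)
        pot = project_range(full, space, world, 2)
        assert pot.area_km2 == pytest.approx(
            world.cell_area_km2()[world.realm_mask(2)].sum())

    def test_niche_area_converges_with_sample_size(self):
        """Estimated potential range approaches truth as occurrences grow."""
        grid = make_world(WorldConfig(nrows=120, ncols=120,
                                      corr_length=(3.0, 2.0, 3.0), seed=6))
        space = build_climate_space(grid, 1, 2)
        clim = grid.realm_climate(1)[:, [0, 2]]
        centre = np.array([np.quantile(clim[:, 0], 0.5), np.quantile(clim[:, 1], 0.5)])
        sd = clim.std(axis=0) * 0.6
        truth = SpeciesTruth("conv", centre, np.diag(sd ** 2), 1, 2, 0.5)
        target = true_suitable_mask(grid, truth).sum()
        errs = []
        for n in (50, 200, 1000):
            occ = make_species(grid, truth, n_native=n, rng=np.random.default_rng(8))
            pot = potential_range(occ, space, grid)
            errs.append(abs(pot.n_cells - target) / target)
        assert errs[2] < errs[0]


class TestTSS:
    @pytest.mark.parametrize("tp,fp,tn,fn,expected", [
        (10, 0, 10, 0, 1.0),           # perfect classifier
        (10, 10, 0, 0, 0.0),           # all-positive on balanced data
        (9, 2, 8, 1, 0.9 + 0.8 - 1),   # sens 0.9, spec 0.8
    ])
    def test_values(self, tp, fp, tn, fn, expected):
        assert tss(tp, fp, tn, fn) == pytest.approx(expected)


class TestCrossValidate:
    def test_report_shape_and_ranges(self, world, space, occurrences):
        rep = crossvalidate(occurrences, world, space, seed=0)
        assert rep.tss.shape == (5, 20)
        assert ((rep.tss >= -1) & (rep.tss <= 1)).all().all()
        assert ((rep.accuracy >= 0) & (rep.accuracy <= 1)).all()

    def test_deterministic(self, world, space, occurrences):
        a = crossvalidate(occurrences, world, space, seed=3)
        b = crossvalidate(occurrences, world, space, seed=3)
        assert np.array_equal(a.accuracy, b.accuracy)
        assert a.tss.equals(b.tss)

    def test_too_few_points(self, world, space, truth):
        occ = make_species(world, truth, n_native=10, rng=np.random.default_rng(1))
        with pytest.raises(ValueError):
            crossvalidate(occ, world, space)

    def test_no_free_admin_units_errors(self, truth):
        grid = make_world(WorldConfig(nrows=30, ncols=30, n_admin_per_realm=1, seed=1))
        clim = grid.realm_climate(1)[:, [0, 2]]
        t = SpeciesTruth("sp", np.median(clim, axis=0),
                         np.diag(clim.std(axis=0) ** 2), 1, 2, 0.5)
        occ = make_species(grid, t, n_native=50, rng=np.random.default_rng(1))
        space = build_climate_space(grid, 1, 2)
        with pytest.raises(ValueError, match="pseudo-absence"):
            crossvalidate(occ, grid, space)
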