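import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from facetshift.occurrences import (
    METERS_PER_DEGREE, UnmodellableSpeciesError, accessible_area, clean_records,
    haversine_m, sample_background, thin_spatially,
)
from facetshift.grids import RasterGrid
from facetshift.synthetic import (
    WorldConfig, generate_world, make_species_pool, sample_occurrences,
    TrueSpecies,
)

STUDY = box(0.0, 40.0, 10.0, 50.0)


def records(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "year", "uncertainty_m"])


class TestCleanRecords:
    def base(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return records([("sp", 5 + rng.uniform(-1, 1), 45 + rng.uniform(-1, 1),
                         2000, 500.0) for _ in range(n)])

    def test_pre_1970_record_removed(self):
        df = self.base(5)
        df.loc[0, "year"] = 1969
        out = clean_records(df, STUDY)
        assert len(out) == 4 and (out["year"] >= 1970).all()

    def test_year_1970_kept(self):
        df = self.base(3)
        df.loc[0, "year"] = 1970
        assert len(clean_records(df, STUDY)) == 3

    def test_duplicate_coordinates_leave_one_survivor(self):
        df = self.base(4)
        df.loc[1, ["lon", "lat"]] = df.loc[0, ["lon", "lat"]]
        assert len(clean_records(df, STUDY)) == 3

    def test_exact_bookkeeping_of_injected_violations(self):
        df = self.base(15)
        bad = records([
            ("sp", 5.0, 45.0, 1950, 100.0),        # too old
            ("sp", 50.0, 45.0, 2000, 100.0),       # outside study area
            ("sp", 5.1, 45.1, 2000, 99000.0),      # too uncertain
            ("sp", df.loc[0, "lon"], df.loc[0, "lat"], 2001, 100.0),  # duplicate
            ("sp", 5.2, 60.0, 2000, 100.0),        # outside (north)
        ])
        out = clean_records(pd.concat([df, bad], ignore_index=True), STUDY)
        assert len(out) == 15

    def test_idempotent(self):
        df = self.base(20)
        df.loc[3, "year"] = 1950
        once = clean_records(df, STUDY)
        twice = clean_records(once, STUDY)
        pd.testing.assert_frame_equal(once, twice)

    def test_order_independent(self):
        df = self.base(10)
        df.loc[4, ["lon", "lat"]] = df.loc[2, ["lon", "lat"]]
        a = clean_records(df, STUDY)
        b = clean_records(df.iloc[::-1].reset_index(drop=True), STUDY)
        key = ["lon", "lat", "year"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True))

    def test_no_survivors_flags_species_unmodellable(self):
        df = records([("sp", 5.0, 45.0, 1950, 100.0)])
        with pytest.raises(UnmodellableSpeciesError):
            clean_records(df, STUDY)


class TestThinning:
    def test_two_close_records_leave_one(self):
        df = records([("sp", 5.0, 45.0, 2000, 1.0), ("sp", 5.0, 45.0005, 2000, 1.0)])
        out = thin_spatially(df, 1.0, 0.1, seed=0)
        assert len(out) == 1

    def test_already_sparse_input_unchanged(self):
        df = records([("sp", 5.0, 45.0, 2000, 1.0), ("sp", 5.0, 46.0, 2000, 1.0),
                      ("sp", 6.0, 45.0, 2000, 1.0)])
        out = thin_spatially(df, 1.0, 0.1, seed=0)
        assert len(out) == 3

    def test_min_distance_guarantee_by_exhaustive_pair_scan(self, rng):
        df = records([("sp", 5 + rng.uniform(0, 0.5), 45 + rng.uniform(0, 0.5),
                       2000, 1.0) for _ in range(200)])
        out = thin_spatially(df, 1.0, 0.1, seed=3)
        lon, lat = out["lon"].to_numpy(), out["lat"].to_numpy()
        thresh = 1.0 * 0.1 * METERS_PER_DEGREE
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert haversine_m(lon[i], lat[i], lon[j], lat[j]) >= thresh

    def test_output_is_subset_of_input(self, rng):
        df = records([("sp", 5 + rng.uniform(0, 0.3), 45 + rng.uniform(0, 0.3),
                       2000, 1.0) for _ in range(50)])
        out = thin_spatially(df, 1.0, 0.1, seed=1)
        assert set(out.index) <= set(df.index)


class TestAccessibleArea:
    def square(self, n_side=5):
        pts = [(5 + i * 0.2, 45 + j * 0.2) for i in range(n_side) for j in range(n_side)]
        return records([("sp", x, y, 2000, 1.0) for x, y in pts])

    def test_buffer_scales_with_flight_period(self):
        df = self.square()
        assert accessible_area(df, 10, outlier_pct=0).buffer_m == 100000.0
        assert accessible_area(df, 4, outlier_pct=0).buffer_m == 40000.0

    def test_hull_of_square_is_square_and_contains_all_points(self):
        from scipy.spatial import ConvexHull

        df = self.square()
        area = accessible_area(df, 5, outlier_pct=0)
        pts = df[["lon", "lat"]].to_numpy()
        oracle = ConvexHull(pts)
        assert area.mcp.area == pytest.approx(oracle.volume, rel=1e-12)
        for x, y in pts:
            assert area.buffered.covers(area.mcp)
            assert area.buffered.contains(area.mcp.representative_point())

    def test_outlier_removal_shrinks_hull(self):
        df = pd.concat([self.square(), records([("sp", 9.0, 49.0, 2000, 1.0)])],
                       ignore_index=True)
        trimmed = accessible_area(df, 5, outlier_pct=0.01)
        untrimmed = accessible_area(df, 5, outlier_pct=0.0)
        assert trimmed.mcp.area < untrimmed.mcp.area

    def test_buffer_distance_is_metric(self):
        # northern edge of the buffered polygon sits ~buffer_m north of the hull
        df = self.square()
        area = accessible_area(df, 10, outlier_pct=0)
        dlat = area.buffered.bounds[3] - area.mcp.bounds[3]
        assert dlat * METERS_PER_DEGREE == pytest.approx(100000.0, rel=0.01)

    def test_collinear_points_rejected(self):
        df = records([("sp", 5.0 + i * 0.1, 45.0, 2000, 1.0) for i in range(5)])
        with pytest.raises(ValueError, match="collinear|fewer"):
            accessible_area(df, 5, outlier_pct=0)


class TestBackground:
    def grid(self):
        return RasterGrid(np.zeros((20, 20)), origin=(4.0, 46.0), cell_size=0.1)

    def area(self, months=5):
        df = TestAccessibleArea().square()
        return accessible_area(df, months, outlier_pct=0)

    def test_twice_the_presences(self):
        bg = sample_background(self.area(), 50, self.grid(), seed=0)
        assert len(bg) == 100

    def test_presence_cells_excluded(self):
        grid = self.grid()
        presence_cells = {(r, c) for r in range(10) for c in range(10)}
        bg = sample_background(self.area(), 20, grid, seed=1,
                               presence_cells=presence_cells)
        assert all((r, c) not in presence_cells for r, c in zip(bg["row"], bg["col"]))

    def test_uniform_cell_frequencies(self):
        from scipy.stats import chisquare

        grid = self.grid()
        area = self.area(months=10)
        draws = [sample_background(area, 100, grid, seed=s) for s in range(50)]
        bg = pd.concat(draws)
        counts = bg.groupby(["row", "col"]).size()
        stat, p = chisquare(counts.to_numpy())
        assert p > 0.01

    def test_too_few_cells_falls_back_with_replacement(self, caplog):
        grid = RasterGrid(np.zeros((2, 2)), origin=(4.95, 45.25), cell_size=0.2)
        df = records([("sp", 5.0, 45.0, 2000, 1.0), ("sp", 5.2, 45.2, 2000, 1.0),
                      ("sp", 5.0, 45.2, 2000, 1.0), ("sp", 5.2, 45.0, 2000, 1.0)])
        area = accessible_area(df, 1, outlier_pct=0)
        with caplog.at_level("WARNING"):
            bg = sample_background(area, 5, grid, seed=0)
        assert len(bg) == 10
        assert any("replacement" in r.message for r in caplog.records)


class TestSyntheticOccurrenceContract:
    def test_zero_dirty_fraction_survives_cleaning(self, small_world):
        sp = make_species_pool(3, (6.0, 12.0), seed=1, n_presences=80)[0]
        occ = sample_occurrences(small_world, sp, seed=5, dirty_fraction=0.0)
        out = clean_records(occ, small_world.study_area_polygon(),
                            max_uncertainty_m=0.1 * METERS_PER_DEGREE)
        assert len(out) == len(occ)

    def test_injected_duplicates_are_exactly_the_removed_ones(self, small_world):
        sp = make_species_pool(3, (6.0, 12.0), seed=1, n_presences=100)[0]
        occ = sample_occurrences(small_world, sp, seed=6, dirty_fraction=0.2)
        n_dirty = (occ["provenance"] != "clean").sum()
        assert len(occ) == sp.n_presences + n_dirty  # conservation
        out = clean_records(occ, small_world.study_area_polygon(),
                            max_uncertainty_m=0.1 * METERS_PER_DEGREE)
        assert set(out["provenance"]) == {"clean"}
        assert len(out) == sp.n_presences

    def test_uniform_suitability_occupies_cells_uniformly(self, small_world):
        from scipy.stats import chisquare

        sp = TrueSpecies("flat", intercept=0.0, coefficients={}, n_presences=600)
        rows_all, cols_all = [], []
        for seed in range(12):
            occ = sample_occurrences(small_world, sp, seed=seed)
            r, c = small_world.grid.indices_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
            rows_all.append(r)
            cols_all.append(c)
        r = np.concatenate(rows_all)
        c = np.concatenate(cols_all)
        land = ~small_world.water_mask
        counts = np.zeros(small_world.grid.shape)
        np.add.at(counts, (r, c), 1)
        stat, p = chisquare(counts[land])
        assert p > 0.01

    def test_too_many_presences_rejected(self, small_world):
        sp = TrueSpecies("big", intercept=0.0, coefficients={}, n_presences=10**6)
        with pytest.raises(ValueError, match="land cells"):
            sample_occurrences(small_world, sp, seed=0)
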