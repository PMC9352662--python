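import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from pescore.features import (
    RandomValueImputer,
    FeatureEncoder,
    assemble_feature_table,
    count_points_in_range,
    impute_missing,
    occurrence_cells,
    rasterize_range,
    zonal_stats,
)
from pescore.grid import GridSpec
from pescore.layers import StressorLayer
from pescore.world import RangePolygon


def brute_force_range_cells(geom, grid: GridSpec) -> set[int]:
    """Exhaustive per-cell positive-area intersection test over the grid.

    Every cell is examined; cells whose rectangle is disjoint from the
    polygon's bounding box are excluded arithmetically (their intersection
    is empty, hence has zero area), the rest by an explicit intersection-
    area computation — a different code path from the implementation.
    """
    gx0, gy0, gx1, gy1 = geom.bounds
    out = set()
    for cell in range(grid.n_cells):
        x0, y0, x1, y1 = grid.cell_bounds(cell)
        if x1 <= gx0 or x0 >= gx1 or y1 <= gy0 or y0 >= gy1:
            continue
        if geom.intersection(box(x0, y0, x1, y1)).area > 0:
            out.add(cell)
    return out


def test_single_cell_rectangle_maps_to_that_cell(grid):
    cell = grid.cell_of(10.2, 40.3)
    geom = box(*grid.cell_bounds(cell))
    cells = rasterize_range([RangePolygon(geom)], grid)
    assert set(cells) == {cell}


def test_tiny_polygon_inside_one_cell(grid):
    geom = box(10.01, 40.01, 10.02, 40.02)
    cells = rasterize_range([RangePolygon(geom)], grid)
    assert set(cells) == {grid.cell_of(10.01, 40.02)}


def test_degenerate_polygon_falls_back_to_centroid_cell(grid):
    # thinner than float noise: no positive-area cell overlap survives
    geom = shapely.geometry.Point(5.25, 5.25).buffer(1e-9)
    cells = rasterize_range([RangePolygon(geom)], grid)
    assert set(cells) == {grid.cell_of(5.25, 5.25)}


def test_non_native_polygons_rejected(grid):
    geom = box(0.1, 0.1, 0.9, 0.9)
    with pytest.raises(ValueError):
        rasterize_range([RangePolygon(geom, origin="introduced")], grid)
    with pytest.raises(ValueError):
        rasterize_range([RangePolygon(geom, presence="extinct")], grid)


def test_rasterize_matches_exhaustive_oracle(rng):
    grid = GridSpec()
    for _ in range(3):
        lon, lat = rng.uniform(-160, 160), rng.uniform(-60, 60)
        geom = shapely.geometry.Point(lon, lat).buffer(rng.uniform(0.3, 2.5), quad_segs=8)
        got = set(rasterize_range([RangePolygon(geom)], grid))
        assert got == brute_force_range_cells(geom, grid)


def test_seasonal_polygons_are_unioned(grid):
    a = box(0.1, 0.1, 0.4, 0.4)
    b = box(3.1, 3.1, 3.4, 3.4)
    cells = rasterize_range(
        [RangePolygon(a, "resident"), RangePolygon(b, "breeding")], grid
    )
    assert set(cells) == {grid.cell_of(0.1, 0.4), grid.cell_of(3.1, 3.4)}


def test_occurrence_binning_examples(grid):
    n, cells = occurrence_cells(np.array([[0.1, 0.1, 2015], [0.2, 0.3, 2016]]), grid)
    assert n == 2 and len(cells) == 1
    # a point exactly on a cell edge belongs to the cell starting there
    _, cells = occurrence_cells(np.array([[0.5, 0.2, 2015]]), grid)
    assert grid.cell_bounds(cells[0])[0] == 0.5


def test_occurrence_binning_matches_brute_force(grid, rng):
    pts = np.column_stack(
        [rng.uniform(-180, 179.9, 1000), rng.uniform(-89.9, 90, 1000), np.full(1000, 2015)]
    )
    _, cells = occurrence_cells(pts, grid)
    brute = {grid.cell_of(x, y) for x, y, _ in pts}
    assert set(cells) == brute


def test_out_of_range_point_reports_index(grid):
    pts = np.array([[0.0, 0.0, 2015], [200.0, 0.0, 2015]])
    with pytest.raises(ValueError, match="index 1"):
        occurrence_cells(pts, grid)


class TestZonalStats:
    def test_constant_layer(self, grid):
        layer = StressorLayer("c", np.full(grid.shape, 3.5), "noise")
        zs = zonal_stats(layer, np.array([0, 1, 2]))
        assert zs.min == zs.max == zs.mean == zs.median == 3.5

    def test_forced_example(self, grid):
        vals = np.full(grid.shape, np.nan).ravel()
        vals[[10, 11, 12, 13]] = [1, 2, 3, 10]
        layer = StressorLayer("x", vals.reshape(grid.shape), "noise")
        zs = zonal_stats(layer, np.array([10, 11, 12, 13]))
        assert (zs.min, zs.max, zs.mean, zs.median) == (1, 10, 4, 2.5)

    def test_all_missing_flagged(self, grid):
        layer = StressorLayer("m", np.full(grid.shape, np.nan), "noise")
        zs = zonal_stats(layer, np.array([5, 6]))
        assert all(np.isnan(v) for v in (zs.min, zs.max, zs.mean, zs.median))

    def test_empty_cells_rejected(self, grid):
        layer = StressorLayer("e", np.zeros(grid.shape), "noise")
        with pytest.raises(ValueError):
            zonal_stats(layer, np.array([], dtype=int))

    def test_matches_direct_recomputation(self, grid, rng):
        vals = rng.standard_normal(grid.shape)
        vals[rng.random(grid.shape) < 0.1] = np.nan
        layer = StressorLayer("r", vals, "noise")
        for _ in range(100):
            cells = rng.choice(grid.n_cells, size=rng.integers(1, 60), replace=False)
            zs = zonal_stats(layer, cells)
            raw = vals.ravel()[cells]
            raw = raw[np.isfinite(raw)]
            if raw.size == 0:
                assert np.isnan(zs.mean)
                continue
            assert zs.min == pytest.approx(raw.min(), abs=1e-12)
            assert zs.max == pytest.approx(raw.max(), abs=1e-12)
            assert zs.mean == pytest.approx(raw.mean(), abs=1e-12)
            assert zs.median == pytest.approx(np.median(raw), abs=1e-12)
            assert zs.min <= zs.mean <= zs.max
            assert zs.min <= zs.median <= zs.max


def test_count_points_examples_and_oracle(grid, rng):
    zero = StressorLayer("dams", np.zeros(grid.shape), "count-like")
    assert count_points_in_range(zero, np.array([1, 2, 3])) == 0
    vals = np.zeros(grid.shape).ravel()
    vals[42] = 7
    layer = StressorLayer("dams", vals.reshape(grid.shape), "count-like")
    assert count_points_in_range(layer, np.array([40, 41, 42])) == 7
    counts = rng.poisson(1.0, grid.shape).astype(float)
    layer = StressorLayer("pp", counts, "count-like")
    cells = rng.choice(grid.n_cells, 500, replace=False)
    assert count_points_in_range(layer, cells) == counts.ravel()[cells].sum()
    with pytest.raises(ValueError):
        count_points_in_range(StressorLayer("x", counts, "noise"), cells)


class TestAssembleTable:
    def test_shape_and_zonal_column_count(self, small_world, small_table):
        n_value_layers = sum(l.kind != "count-like" for l in small_world.layers)
        zonal = [c for c in small_table.columns if c.endswith(("_range", "_occ"))
                 and not c.startswith(("range_extent", "n_"))]
        assert len(small_table) == len(small_world.species)
        assert len(zonal) == n_value_layers * 4 * 2

    def test_no_occurrence_species_have_missing_occ_columns(self, small_world, small_table):
        with_occ = {o.species_id for o in small_world.occurrences}
        without = small_table.loc[~small_table.species_id.isin(with_occ)]
        assert len(without) > 0
        assert (without.n_occurrence_points == 0).all()
        assert without.n_occurrence_cells.isna().all()
        occ_cols = [c for c in small_table.columns if c.endswith("_occ")]
        assert without[occ_cols].isna().all().all()

    def test_order_invariance(self, small_world, small_range_cells):
        w = small_world
        fwd = assemble_feature_table(w.species, w.occurrences, w.layers, w.grid, small_range_cells)
        rev = assemble_feature_table(w.species[::-1], w.occurrences[::-1], w.layers, w.grid, small_range_cells)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_rerun_is_byte_identical(self, small_world, small_range_cells, tmp_path):
        w = small_world
        a = assemble_feature_table(w.species, w.occurrences, w.layers, w.grid, small_range_cells)
        b = assemble_feature_table(w.species, w.occurrences, w.layers, w.grid, small_range_cells)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_unknown_occurrence_id_reported(self, small_world, small_range_cells):
        from pescore.world import OccurrenceSet

        w = small_world
        bad = w.occurrences + [OccurrenceSet("sp_ghost", np.array([[0.0, 0.0, 2015]]))]
        with pytest.raises(ValueError, match="sp_ghost"):
            assemble_feature_table(w.species, bad, w.layers, w.grid, small_range_cells)


class TestImputation:
    def make(self):
        return pd.DataFrame(
            {
                "a": [1.0, np.nan, 3.0, np.nan],
                "b": [np.nan, np.nan, np.nan, np.nan],
                "c": ["x", "y", "z", "w"],
            }
        )

    def test_no_missing_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        pd.testing.assert_frame_equal(impute_missing(df, seed=1), df)

    def test_imputed_values_come_from_observed_pool(self):
        out = impute_missing(self.make(), seed=5)
        assert set(out["a"]) <= {1.0, 3.0}
        assert (out["a"].iloc[[0, 2]] == [1.0, 3.0]).all()  # observed untouched

    def test_all_missing_column_dropped(self):
        out = impute_missing(self.make(), seed=5)
        assert "b" not in out.columns

    def test_seeded_determinism(self):
        df = self.make()
        pd.testing.assert_frame_equal(impute_missing(df, 7), impute_missing(df, 7))

    def test_pools_fitted_on_training_rows_only(self):
        df = pd.DataFrame({"a": [10.0, 20.0, np.nan, np.nan]}, index=list("wxyz"))
        imp = RandomValueImputer(3).fit(df, fit_index=["w"])
        out = imp.transform(df)
        assert (out.loc[["y", "z"], "a"] == 10.0).all()


def test_encoder_one_hot_blocks_and_determinism(small_table):
    enc = FeatureEncoder().fit(small_table)
    X = enc.transform(small_table)
    assert list(X.columns) == enc.columns_
    fam_cols = [c for c in X.columns if c.startswith("family=")]
    assert fam_cols and all(enc.blocks[c] == "family" for c in fam_cols)
    np.testing.assert_array_equal(
        X[fam_cols].sum(axis=1).to_numpy(), np.ones(len(X))
    )
    X2 = FeatureEncoder().fit(small_table).transform(small_table)
    pd.testing.assert_frame_equal(X, X2)
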