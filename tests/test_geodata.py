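import numpy as np
import pytest

from coastpop.geodata import (GridSpec, Raster, distance_to_coast, read_raster,
                              resample, slope_from_dem, write_raster,
                              zonal_aggregate)


def spec_of(n_rows, n_cols, cell=100.0, crs="t"):
    return GridSpec(n_rows, n_cols, origin_x=0.0, origin_y=n_rows * cell,
                    cell_size=cell, crs_tag=crs)


class TestRasterIO:
    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(7, 5))
        vals[2, 3] = np.nan
        r = Raster(GridSpec(7, 5, origin_x=123.25, origin_y=987.5,
                            cell_size=33.5, crs_tag="albers-synthetic"), vals)
        path = tmp_path / "r.tif"
        write_raster(r, path)
        back = read_raster(path)
        assert back.spec == r.spec
        np.testing.assert_array_equal(back.values, r.values)
        np.testing.assert_array_equal(back.mask(), r.mask())

    def test_roundtrip_integer_labels(self, tmp_path):
        vals = np.array([[0, 3], [7, 0]], dtype=np.int32)
        r = Raster(spec_of(2, 2), vals, 0)
        write_raster(r, tmp_path / "lab.tif")
        back = read_raster(tmp_path / "lab.tif")
        np.testing.assert_array_equal(back.values, vals)
        assert back.nodata == 0
        np.testing.assert_array_equal(back.mask(), vals != 0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raster(tmp_path / "absent.tif")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Raster(spec_of(2, 2), np.zeros((3, 2)))


class TestResample:
    def test_identity_spec_is_identity(self):
        rng = np.random.default_rng(1)
        src = Raster(spec_of(6, 6), rng.normal(size=(6, 6)))
        for method in ("nearest", "bilinear"):
            out = resample(src, src.spec, method)
            np.testing.assert_array_equal(out.values, src.values)

    def test_bilinear_midpoint_is_corner_mean(self):
        src = Raster(GridSpec(2, 2, 0.0, 2.0, 1.0, "t"),
                     np.array([[0.0, 2.0], [4.0, 6.0]]))
        target = GridSpec(1, 1, 0.0, 2.0, 2.0, "t")  # centre (1,1) = src midpoint
        out = resample(src, target, "bilinear")
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_nearest_checkerboard_upsample_matches_bruteforce(self):
        cell = 2.0
        src_vals = np.indices((4, 4)).sum(axis=0) % 2
        src = Raster(GridSpec(4, 4, 0.0, 8.0, cell, "t"), src_vals.astype(float))
        target = GridSpec(8, 8, 0.0, 8.0, 1.0, "t")
        out = resample(src, target, "nearest")
        # each source value replicated in a 2x2 block
        np.testing.assert_array_equal(out.values, np.kron(src_vals, np.ones((2, 2))))
        # brute-force nearest-centre oracle (first-match argmin, row-major)
        sx, sy = src.spec.cell_centers()
        tx, ty = target.cell_centers()
        oracle = np.zeros(target.shape)
        for r in range(8):
            for c in range(8):
                d2 = (sx - tx[r, c]) ** 2 + (sy - ty[r, c]) ** 2
                idx = np.unravel_index(np.argmin(d2), d2.shape)
                oracle[r, c] = src.values[idx]
        np.testing.assert_array_equal(out.values, oracle)

    def test_bilinear_propagates_nodata(self):
        vals = np.array([[0.0, np.nan], [4.0, 6.0]])
        src = Raster(GridSpec(2, 2, 0.0, 2.0, 1.0, "t"), vals)
        target = GridSpec(1, 1, 0.0, 2.0, 2.0, "t")
        out = resample(src, target, "bilinear")
        assert np.isnan(out.values[0, 0])

    def test_crs_mismatch(self):
        src = Raster(spec_of(2, 2, crs="a"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="CRS"):
            resample(src, spec_of(2, 2, crs="b"), "nearest")

    def test_empty_overlap(self):
        src = Raster(spec_of(2, 2), np.zeros((2, 2)))
        far = GridSpec(2, 2, origin_x=1e7, origin_y=1e7, cell_size=100.0, crs_tag="t")
        with pytest.raises(ValueError, match="overlap"):
            resample(src, far, "nearest")


class TestSlope:
    def test_flat_dem_zero_slope(self):
        dem = Raster(spec_of(5, 5), np.full((5, 5), 42.0))
        out = slope_from_dem(dem)
        np.testing.assert_allclose(out.values, 0.0)

    def test_unit_gradient_is_45_degrees(self):
        # plane rising 100 m per 100 m cell eastward -> |grad| = 1
        cols = np.arange(6) * 100.0
        dem = Raster(spec_of(6, 6), np.tile(cols, (6, 1)))
        out = slope_from_dem(dem)
        np.testing.assert_allclose(out.values[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_matches_independent_horn_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.normal(scale=30.0, size=(10, 10))
        cell = 100.0
        dem = Raster(spec_of(10, 10, cell=cell), z)
        out = slope_from_dem(dem)
        for r in range(1, 9):
            for c in range(1, 9):
                gx = ((z[r - 1, c + 1] + 2 * z[r, c + 1] + z[r + 1, c + 1])
                      - (z[r - 1, c - 1] + 2 * z[r, c - 1] + z[r + 1, c - 1])) / (8 * cell)
                gy = ((z[r + 1, c - 1] + 2 * z[r + 1, c] + z[r + 1, c + 1])
                      - (z[r - 1, c - 1] + 2 * z[r - 1, c] + z[r - 1, c + 1])) / (8 * cell)
                expect = np.degrees(np.arctan(np.hypot(gx, gy)))
                assert out.values[r, c] == pytest.approx(expect, abs=1e-9)

    def test_nodata_propagates(self):
        z = np.full((4, 4), 1.0)
        z[1, 1] = np.nan
        out = slope_from_dem(Raster(spec_of(4, 4), z))
        assert np.isnan(out.values[:3, :3]).all()
        assert np.isfinite(out.values[3, 3])


class TestZonal:
    def test_simple_mean(self):
        spec = spec_of(1, 3)
        labels = Raster(spec, np.array([[1, 1, 2]]), 0)
        values = Raster(spec, np.array([[2.0, 4.0, 6.0]]))
        out = zonal_aggregate(values, labels, "mean")
        assert out[1] == 3.0 and out[2] == 6.0

    def test_all_nodata_label_flagged_missing(self):
        spec = spec_of(1, 3)
        labels = Raster(spec, np.array([[1, 2, 2]]), 0)
        values = Raster(spec, np.array([[5.0, np.nan, np.nan]]))
        out = zonal_aggregate(values, labels, "sum")
        assert out[1] == 5.0
        assert np.isnan(out[2])

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(3)
        spec = spec_of(100, 100)
        lab = rng.integers(0, 12, size=(100, 100))
        vals = rng.normal(size=(100, 100))
        vals[rng.random((100, 100)) < 0.1] = np.nan
        labels = Raster(spec, lab, 0)
        values = Raster(spec, vals)
        for stat in ("mean", "sum", "count"):
            out = zonal_aggregate(values, labels, stat)
            acc: dict[int, list] = {}
            for r in range(100):
                for c in range(100):
                    if lab[r, c] != 0 and np.isfinite(vals[r, c]):
                        acc.setdefault(int(lab[r, c]), []).append(vals[r, c])
            for uid in out.index:
                vals_u = acc.get(int(uid), [])
                if stat == "count":
                    assert out[uid] == len(vals_u)
                elif not vals_u:
                    assert np.isnan(out[uid])
                elif stat == "sum":
                    assert out[uid] == pytest.approx(np.sum(vals_u), rel=1e-12, abs=1e-12)
                else:
                    assert out[uid] == pytest.approx(np.mean(vals_u), rel=1e-15)

    def test_sum_conserves_global_total(self):
        rng = np.random.default_rng(4)
        spec = spec_of(40, 40)
        lab = rng.integers(1, 9, size=(40, 40))  # every cell labelled
        vals = rng.random((40, 40))
        out = zonal_aggregate(Raster(spec, vals), Raster(spec, lab, 0), "sum")
        assert out.sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_misaligned_rejected(self):
        a = Raster(spec_of(2, 2), np.zeros((2, 2)))
        b = Raster(spec_of(2, 2, cell=50.0), np.zeros((2, 2), dtype=int), 0)
        with pytest.raises(ValueError, match="aligned"):
            zonal_aggregate(a, b, "mean")


class TestDistanceToCoast:
    def test_adjacent_land_cell(self):
        spec = spec_of(1, 3, cell=100.0)
        land = Raster(spec, np.array([[0, 1, 1]], dtype=np.uint8))
        out = distance_to_coast(land)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(100.0)
        assert out.values[0, 2] == pytest.approx(200.0)

    def test_matches_allpairs_bruteforce(self):
        rng = np.random.default_rng(5)
        mask = rng.random((30, 30)) < 0.7
        mask[0, 0] = False  # guarantee sea
        spec = spec_of(30, 30, cell=50.0)
        out = distance_to_coast(Raster(spec, mask.astype(np.uint8)))
        sea = np.argwhere(~mask)
        for r in range(30):
            for c in range(30):
                d = np.sqrt(((sea - [r, c]) ** 2).sum(axis=1)).min() * 50.0
                expect = 0.0 if not mask[r, c] else d
                assert out.values[r, c] == pytest.approx(expect, abs=1e-9)

    def test_transposition_symmetry(self):
        rng = np.random.default_rng(6)
        mask = rng.random((20, 25)) < 0.6
        mask[3, 4] = False
        a = distance_to_coast(Raster(spec_of(20, 25), mask.astype(np.uint8)))
        b = distance_to_coast(Raster(spec_of(25, 20), mask.T.astype(np.uint8)))
        np.testing.assert_allclose(a.values, b.values.T)

    def test_all_land_rejected(self):
        with pytest.raises(ValueError, match="sea"):
            distance_to_coast(Raster(spec_of(3, 3), np.ones((3, 3), dtype=np.uint8)))
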