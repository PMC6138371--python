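"""Grid geometry, raster I/O round-trips and source-to-feather transforms."""

import numpy as np
import pytest

from isomatch import (CalibrationModel, GridSpec, IsoscapeRaster, IsoscapeStack,
                      apply_discrimination, calibrate_hydrogen, cell_area_km2,
                      load_isoscape, regrid, save_isoscape)
from isomatch.grid import cell_areas_km2

from conftest import plane_raster


class TestGrid:
    def test_cell_centers_are_box_midpoints(self, grid10):
        assert grid10.center_of(0, 0) == (0.5, 9.5)
        assert grid10.center_of(9, 9) == (9.5, 0.5)

    def test_half_open_cell_lookup(self, grid10):
        # west/north edges belong to the cell, east/south edges to the next
        assert grid10.cell_of(0.0, 10.0) == (0, 0)
        assert grid10.cell_of(1.0, 9.0) == (1, 1)
        with pytest.raises(ValueError):
            grid10.cell_of(11.0, 5.0)

    def test_lookup_inverts_centers(self, grid10):
        for rc in [(0, 0), (3, 7), (9, 9)]:
            assert grid10.cell_of(*grid10.center_of(*rc)) == rc

    def test_equator_cell_area(self):
        g = GridSpec(lon_min=0, lat_max=0.165, n_rows=1, n_cols=1, resolution=0.33)
        # (0.33 * 111.32)^2 at latitude 0
        assert cell_area_km2(g, 0) == pytest.approx(1349.5, abs=0.1)

    def test_area_halves_at_60_degrees(self):
        g = GridSpec(lon_min=0, lat_max=60.165, n_rows=366, n_cols=1, resolution=0.33)
        eq_row = np.argmin(np.abs(g.lat_centers()))
        assert cell_area_km2(g, 0) == pytest.approx(
            0.5 * cell_area_km2(g, int(eq_row)), rel=1e-3)

    def test_area_decreases_with_latitude(self):
        g = GridSpec(lon_min=0, lat_max=60.0, n_rows=100, n_cols=1, resolution=0.33)
        areas = [cell_area_km2(g, r) for r in range(g.n_rows)]
        assert np.all(np.diff(areas) > 0)  # rows go north -> south here

    def test_region_cell_count_matches_paper_scale(self):
        # a ~149,020 km^2 region near 5-10N spans on the order of 107-115 cells
        g = GridSpec(lon_min=0, lat_max=10.0, n_rows=16, n_cols=60, resolution=0.33)
        mean_area = cell_areas_km2(g).mean()
        n_cells = 149020 / mean_area
        assert 105 <= n_cells <= 115

    def test_summed_areas_match_mean_times_count(self):
        g = GridSpec(lon_min=0, lat_max=30.0, n_rows=60, n_cols=40, resolution=0.5)
        areas = cell_areas_km2(g)
        mask = np.random.default_rng(0).random(g.shape) < 0.4
        total = areas[mask].sum()
        assert total == pytest.approx(areas.mean() * mask.sum(), rel=0.005)


class TestIO:
    def test_constant_roundtrip(self, constant_raster, tmp_path):
        p = save_isoscape(constant_raster, tmp_path / "c.asc")
        back = load_isoscape(p, "2H")
        assert back.valid_mask.all()
        assert np.allclose(back.mean, -40.0)
        assert back.grid.same_geometry(constant_raster.grid)

    def test_nodata_cells_become_invalid(self, grid10, tmp_path):
        mean = np.full(grid10.shape, 5.0)
        mask = np.ones(grid10.shape, bool)
        for rc in [(0, 0), (3, 4), (9, 9)]:
            mask[rc] = False
        r = IsoscapeRaster(grid=grid10, isotope="13C", mean=mean, valid_mask=mask)
        back = load_isoscape(save_isoscape(r, tmp_path / "n.asc"), "13C")
        assert (~back.valid_mask).sum() == 3
        assert not back.valid_mask[0, 0] and not back.valid_mask[3, 4]

    def test_random_roundtrip_precision(self, grid10, tmp_path):
        rng = np.random.default_rng(3)
        r = IsoscapeRaster(grid=grid10, isotope="15N",
                           mean=rng.normal(4, 3, grid10.shape),
                           sd=rng.uniform(0.2, 2, grid10.shape))
        back = load_isoscape(save_isoscape(r, tmp_path / "r.asc"), "15N")
        assert np.abs(back.mean - r.mean).max() <= 1e-6
        assert np.abs(back.sd - r.sd).max() <= 1e-6  # sidecar SD raster

    def test_projected_crs_rejected(self, constant_raster, tmp_path):
        import json
        p = save_isoscape(constant_raster, tmp_path / "p.asc")
        side = tmp_path / "p.asc.json"
        meta = json.loads(side.read_text())
        meta["crs"] = "EPSG:32633"
        side.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="not geographic"):
            load_isoscape(p, "2H")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_isoscape(tmp_path / "absent.asc", "2H")


class TestCalibration:
    def test_identity(self, constant_raster):
        out = calibrate_hydrogen(constant_raster, CalibrationModel(1.0, 0.0, 0.0))
        assert np.allclose(out.mean, constant_raster.mean)
        assert np.allclose(out.sd, 0.0)

    def test_hand_arithmetic(self, constant_raster):
        out = calibrate_hydrogen(constant_raster,
                                 CalibrationModel(h_slope=0.95, h_intercept=-20.0))
        assert np.allclose(out.mean, 0.95 * -40.0 - 20.0)  # -58.0

    def test_sd_quadrature(self, grid10):
        r = IsoscapeRaster(grid=grid10, isotope="2H", mean=np.zeros(grid10.shape),
                           sd=np.full(grid10.shape, 5.0))
        out = calibrate_hydrogen(r, CalibrationModel(h_residual_sd=12.0))
        assert np.allclose(out.sd, 13.0)  # sqrt(25 + 144)

    def test_wrong_isotope_rejected(self, grid10):
        r = IsoscapeRaster(grid=grid10, isotope="13C", mean=np.zeros(grid10.shape))
        with pytest.raises(ValueError):
            calibrate_hydrogen(r, CalibrationModel())

    def test_affine_composition(self, constant_raster):
        a, b, c, d = 0.9, -12.0, 1.1, 4.0
        two_step = calibrate_hydrogen(
            calibrate_hydrogen(constant_raster, CalibrationModel(a, b)),
            CalibrationModel(c, d))
        one_step = calibrate_hydrogen(constant_raster, CalibrationModel(c * a, c * b + d))
        assert np.abs(two_step.mean - one_step.mean).max() <= 1e-9

    def test_commutes_with_masking(self, grid10):
        rng = np.random.default_rng(5)
        mask = rng.random(grid10.shape) < 0.7
        r = IsoscapeRaster(grid=grid10, isotope="2H",
                           mean=rng.normal(-50, 10, grid10.shape))
        cal = CalibrationModel(0.9, -10.0, 5.0)
        a = calibrate_hydrogen(r.masked(mask), cal)
        b = calibrate_hydrogen(r, cal).masked(mask)
        assert np.array_equal(a.valid_mask, b.valid_mask)
        assert np.allclose(a.mean[a.valid_mask], b.mean[b.valid_mask])

    @pytest.mark.parametrize("isotope,value,offset,expected", [
        ("13C", -25.0, 2.0, -23.0),
        ("15N", 4.0, 5.0, 9.0),
    ])
    def test_discrimination_offsets(self, grid10, isotope, value, offset, expected):
        r = IsoscapeRaster(grid=grid10, isotope=isotope,
                           mean=np.full(grid10.shape, value))
        out = apply_discrimination(r, offset)
        assert np.allclose(out.mean, expected)

    def test_discrimination_identity(self, grid10):
        r = IsoscapeRaster(grid=grid10, isotope="13C",
                           mean=np.full(grid10.shape, -21.5))
        out = apply_discrimination(r, 0.0, 0.0)
        assert np.allclose(out.mean, r.mean)
        assert np.allclose(out.sd, 0.0)

    def test_nonfinite_offset_rejected(self, grid10):
        r = IsoscapeRaster(grid=grid10, isotope="15N", mean=np.zeros(grid10.shape))
        with pytest.raises(ValueError):
            apply_discrimination(r, np.nan)


class TestRegrid:
    def test_identity_on_same_grid(self, grid10):
        r = plane_raster(grid10, b_lon=2.0, b_lat=-1.0)
        out = regrid(r, grid10, "bilinear")
        assert np.allclose(out.mean[out.valid_mask], r.mean[r.valid_mask])

    @pytest.mark.parametrize("method", ["nearest", "bilinear"])
    def test_constant_preserved_on_finer_grid(self, grid10, constant_raster, method):
        fine = GridSpec(lon_min=2.0, lat_max=8.0, n_rows=12, n_cols=12, resolution=0.5)
        out = regrid(constant_raster, fine, method)
        assert np.allclose(out.mean[out.valid_mask], -40.0)
        assert out.valid_mask.all()

    def test_bilinear_plane_exact_at_2x(self, grid10):
        r = plane_raster(grid10, a=3.0, b_lon=1.5, b_lat=-0.7)
        fine = GridSpec(lon_min=1.0, lat_max=9.0, n_rows=16, n_cols=16, resolution=0.5)
        out = regrid(r, fine, "bilinear")
        lon = fine.lon_centers()[None, :]
        lat = fine.lat_centers()[:, None]
        expected = 3.0 + 1.5 * lon + -0.7 * lat
        assert np.abs(out.mean - expected)[out.valid_mask].max() <= 1e-9

    def test_bilinear_never_extrapolates(self, grid10):
        r = plane_raster(grid10)
        wide = GridSpec(lon_min=-5.0, lat_max=15.0, n_rows=30, n_cols=30, resolution=1.0)
        out = regrid(r, wide, "bilinear")
        lon = wide.lon_centers()[None, :] * np.ones(wide.shape)
        lat = wide.lat_centers()[:, None] * np.ones(wide.shape)
        outside = (lon < 0.5) | (lon > 9.5) | (lat < 0.5) | (lat > 9.5)
        assert not out.valid_mask[outside].any()

    def test_disjoint_extent_rejected(self, grid10, constant_raster):
        far = GridSpec(lon_min=100.0, lat_max=10.0, n_rows=5, n_cols=5, resolution=1.0)
        with pytest.raises(ValueError, match="disjoint"):
            regrid(constant_raster, far)


class TestStack:
    def test_joint_mask_is_conjunction(self, grid10):
        rng = np.random.default_rng(2)
        masks = [rng.random(grid10.shape) < 0.8 for _ in range(3)]
        layers = [
            IsoscapeRaster(grid=grid10, isotope=iso, mean=np.zeros(grid10.shape),
                           valid_mask=m)
            for iso, m in zip(("2H", "13C", "15N"), masks)
        ]
        stack = IsoscapeStack(layers)
        assert np.array_equal(stack.joint_valid_mask, masks[0] & masks[1] & masks[2])

    def test_duplicate_isotopes_rejected(self, grid10, constant_raster):
        with pytest.raises(ValueError):
            IsoscapeStack([constant_raster, constant_raster])
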