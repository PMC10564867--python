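"""Synthetic forcing generator and NetCDF ingest."""

import numpy as np
import pytest
import xarray as xr

import thermodiv as td
from thermodiv.synthetic_paleoclimate import (
    DEFAULT_AGES,
    ConfigurationError,
    default_paleogeography,
    load_climate_field,
    read_gcm_field,
    tropical_band_mean,
    write_climate_field,
    zonal_profile,
)


class TestScenarios:
    def test_proxy_cooling_endpoints(self):
        sc = td.build_scenario("proxy-cooling")
        assert sc.tropical_sst(490.0) == 45.0
        assert sc.tropical_sst(430.0) == 30.0
        ssts = [sc.tropical_sst(a) for a in sc.ages]  # ages run oldest first
        assert all(a >= b for a, b in zip(ssts, ssts[1:]))

    def test_intermediate_ages_interpolate(self):
        sc = td.build_scenario("proxy-cooling", [485.0, 465.0])
        assert sc.tropical_sst(485.0) == pytest.approx((45 + 42.5) / 2)
        assert sc.tropical_sst(465.0) == pytest.approx((40 + 37) / 2)

    @pytest.mark.parametrize("name, value", [("constant-30", 30.0),
                                             ("constant-40", 40.0)])
    def test_constant_scenarios(self, name, value):
        sc = td.build_scenario(name)
        assert all(sc.tropical_sst(a) == value for a in sc.ages)

    def test_unknown_scenario_raises(self):
        with pytest.raises(ConfigurationError):
            td.build_scenario("pliocene")

    def test_ages_outside_period_raise(self):
        with pytest.raises(ConfigurationError):
            td.build_scenario("constant-30", [500.0])


class TestZonalProfile:
    def test_reference_values(self):
        assert zonal_profile(45.0, -1.8, 1.0, 0.0) == pytest.approx(45.0)
        assert zonal_profile(45.0, -1.8, 1.0, 90.0) == pytest.approx(-1.8)
        assert zonal_profile(45.0, -1.8, 1.0, 60.0) == pytest.approx(21.6)

    def test_symmetric_and_monotone_in_abs_latitude(self):
        lats = np.linspace(0, 90, 91)
        t = zonal_profile(38.0, 2.0, 1.7, lats)
        assert np.allclose(t, zonal_profile(38.0, 2.0, 1.7, -lats))
        assert np.all(np.diff(t) <= 1e-12)

    def test_clamped_at_seawater_freezing(self):
        t = zonal_profile(10.0, -10.0, 1.0, np.array([80.0, 90.0]))
        assert np.all(t >= -1.8)

    def test_invalid_exponent_raises(self):
        with pytest.raises(ConfigurationError):
            zonal_profile(30.0, -1.8, 0.0, 10.0)


class TestGeneratedFields:
    def test_determinism_bit_identical(self, proxy_scenario):
        a = td.generate_climate_field(proxy_scenario, 470.0, noise_sd=0.5, seed=9)
        b = td.generate_climate_field(proxy_scenario, 470.0, noise_sd=0.5, seed=9)
        assert np.array_equal(a.temperature, b.temperature)
        c = td.generate_climate_field(proxy_scenario, 470.0, noise_sd=0.5, seed=10)
        assert not np.array_equal(a.temperature, c.temperature)

    def test_unconfigured_age_raises(self, proxy_scenario):
        with pytest.raises(ConfigurationError):
            td.generate_climate_field(proxy_scenario, 489.0)

    def test_pointwise_cooling_under_proxy_scenario(self, proxy_scenario):
        fields = [td.generate_climate_field(proxy_scenario, a, noise_sd=0.0)
                  for a in DEFAULT_AGES]
        for older, younger in zip(fields, fields[1:]):
            assert np.all(younger.temperature <= older.temperature + 1e-12)

    def test_constant_scenarios_only_masks_drift(self):
        sc = td.build_scenario("constant-30")
        f1 = td.generate_climate_field(sc, 490.0, noise_sd=0.0)
        f2 = td.generate_climate_field(sc, 430.0, noise_sd=0.0)
        assert np.allclose(f1.temperature, f2.temperature)
        assert not np.array_equal(f1.land_mask, f2.land_mask)

    def test_masks_are_consistent(self, proxy_scenario):
        f = td.generate_climate_field(proxy_scenario, 460.0, noise_sd=0.0)
        assert not (f.shelf_mask & f.land_mask).any()
        assert f.shelf_mask.any() and f.land_mask.any()
        # region labels cover exactly land + shelf
        labelled = f.region_codes > 0
        assert np.array_equal(labelled, f.land_mask | f.shelf_mask)

    @pytest.mark.parametrize("name, age, expected", [
        ("proxy-cooling", 490.0, 45.0),
        ("proxy-cooling", 430.0, 30.0),
        ("constant-40", 460.0, 40.0),
    ])
    def test_tropical_band_mean_matches_scenario(self, name, age, expected):
        sc = td.build_scenario(name)
        f = td.generate_climate_field(sc, age, noise_sd=0.0)
        assert tropical_band_mean(f) == pytest.approx(expected, abs=0.5)


class TestPaleogeography:
    def test_baltica_drifts_north_monotonically(self):
        track = default_paleogeography().block("Baltica")
        ages = np.array(track.ages)
        centers = np.array(track.center_lat)
        order = np.argsort(-ages)  # oldest -> youngest
        assert np.all(np.diff(centers[order]) > 0)

    def test_blocks_never_overlap_on_default_grid(self):
        geo = default_paleogeography()
        grid = td.GridSpec()
        for age in DEFAULT_AGES:
            land, shelf, region = geo.rasterize(grid, age)  # raises on overlap
            assert not (land & shelf).any()

    def test_interpolated_age_between_slices(self):
        geo = default_paleogeography()
        b485 = geo.block("Baltica").bounds(485.0)
        b490 = geo.block("Baltica").bounds(490.0)
        b480 = geo.block("Baltica").bounds(480.0)
        assert b490[0] < b485[0] < b480[0]


class TestNetCDF:
    def test_climate_field_round_trip(self, proxy_scenario, tmp_path):
        f = td.generate_climate_field(proxy_scenario, 450.0, noise_sd=0.25,
                                      seed=3)
        path = tmp_path / "field.nc"
        write_climate_field(f, path)
        back = load_climate_field(path)
        assert np.allclose(back.temperature, f.temperature)
        assert np.array_equal(back.shelf_mask, f.shelf_mask)
        assert back.age == f.age and back.scenario == f.scenario

    def _write(self, tmp_path, temp, units="degC", depths=None, bathy=None):
        coords = {"lat": np.linspace(-75, 75, temp.shape[-2]),
                  "lon": np.linspace(0, 337.5, temp.shape[-1])}
        data = {}
        if depths is not None:
            coords["depth"] = np.asarray(depths, float)
            data["temp"] = (("depth", "lat", "lon"), temp, {"units": units})
        else:
            data["temp"] = (("lat", "lon"), temp, {"units": units})
        if bathy is not None:
            data["bathymetry"] = (("lat", "lon"), bathy)
        path = tmp_path / "gcm.nc"
        xr.Dataset(data, coords=coords).to_netcdf(path, engine="scipy")
        return path

    def test_single_shallow_level_passes_through(self, tmp_path):
        t = np.full((1, 8, 8), 12.5)
        path = self._write(tmp_path, t, depths=[50.0],
                           bathy=np.full((8, 8), 100.0))
        f = read_gcm_field(path)
        assert np.allclose(f.temperature, 12.5)
        assert f.shelf_mask.all()

    def test_two_equal_thickness_levels_average(self, tmp_path):
        t = np.empty((2, 8, 8))
        t[0], t[1] = 10.0, 20.0
        path = self._write(tmp_path, t, depths=[25.0, 75.0],
                           bathy=np.full((8, 8), 100.0))
        f = read_gcm_field(path)
        assert np.allclose(f.temperature, 15.0)

    def test_no_level_within_100m_raises(self, tmp_path):
        path = self._write(tmp_path, np.full((1, 8, 8), 5.0), depths=[150.0],
                           bathy=np.full((8, 8), 400.0))
        with pytest.raises(IOError, match="no vertical levels"):
            read_gcm_field(path)

    def test_kelvin_is_converted(self, tmp_path):
        path = self._write(tmp_path, np.full((8, 8), 293.15), units="K",
                           bathy=np.full((8, 8), 150.0))
        f = read_gcm_field(path)
        assert np.allclose(f.temperature, 20.0)

    def test_unknown_units_raise(self, tmp_path):
        path = self._write(tmp_path, np.full((8, 8), 68.0), units="degF",
                           bathy=np.full((8, 8), 150.0))
        with pytest.raises(IOError, match="units"):
            read_gcm_field(path)

    def test_missing_variable_raises(self, tmp_path):
        path = self._write(tmp_path, np.full((8, 8), 10.0),
                           bathy=np.full((8, 8), 100.0))
        with pytest.raises(IOError, match="no variable"):
            read_gcm_field(path, temp_var="theta")

    def test_bathymetry_defines_shelf_and_land(self, tmp_path):
        bathy = np.full((8, 8), 1000.0)
        bathy[2, :] = 120.0   # shelf
        bathy[3, :] = 0.0     # land
        path = self._write(tmp_path, np.full((8, 8), 10.0), bathy=bathy)
        f = read_gcm_field(path)
        assert f.shelf_mask[2].all() and not f.shelf_mask[4].any()
        assert f.land_mask[3].all()
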