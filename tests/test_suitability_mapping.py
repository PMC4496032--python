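"""Climatology, Cressman interpolation and suitability-map generation."""

import numpy as np
import pandas as pd
import pytest

from thermogerm import germination_data as gd
from thermogerm import suitability_mapping as sm
from thermogerm import synthetic_data as sdata
from thermogerm.response_models import fit_ols


def _station_frame(rows):
    return pd.DataFrame(
        rows, columns=["station_id", "lon", "lat", "month", "tmin_mean_c", "tmax_mean_c"]
    )


class TestClimatology:
    def test_constant_daily_records_average_to_themselves(self):
        rows = [
            ("A", 100.0, 30.0, m, 10.0, 20.0) for m in range(1, 13) for _ in range(30)
        ]
        clim = sm.monthly_climatology(_station_frame(rows))
        assert len(clim) == 12
        assert np.all(clim["tmin_mean_c"] == 10.0)
        assert np.all(clim["tmax_mean_c"] == 20.0)

    def test_repeated_years_idempotent(self):
        base = [("A", 100.0, 30.0, m, float(m), m + 5.0) for m in range(1, 13)]
        one = sm.monthly_climatology(_station_frame(base))
        many = sm.monthly_climatology(_station_frame(base * 25))
        pd.testing.assert_frame_equal(one, many)

    def test_missing_month_absent_from_output(self):
        rows = [("A", 100.0, 30.0, m, 5.0, 10.0) for m in range(1, 12)]  # no Dec
        clim = sm.monthly_climatology(_station_frame(rows))
        assert set(clim["month"]) == set(range(1, 12))

    def test_accepts_station_records(self):
        records = sdata.simulate_station_network(5, seed=0)
        clim = sm.monthly_climatology(records)
        assert len(clim) == 5 * 12


class TestCressman:
    SPEC = sm.GridSpec(lon0=100.0, lat0=30.0, step=0.5, nlon=9, nlat=9)

    def test_single_station_at_node_converges_to_station_value(self):
        # station exactly on the central grid node
        grid = sm.cressman(
            [(102.0, 32.0, 17.0)], self.SPEC, radii_km=(500.0, 200.0, 100.0)
        )
        ilat = ilon = 4
        assert grid.values[ilat, ilon] == pytest.approx(17.0, abs=1e-9)

    def test_weight_formula_endpoints(self):
        r = 500.0
        w = lambda d: (r**2 - d**2) / (r**2 + d**2)
        assert w(0.0) == 1.0
        assert w(r) == 0.0

    def test_two_equidistant_stations_average(self):
        """One pass, symmetric stations: node correction is the mean residual."""
        spec = sm.GridSpec(lon0=0.0, lat0=-1.0, step=1.0, nlon=1, nlat=3)
        # stations symmetric about the middle node (0, 0)
        stations = [(0.0, 0.5, 4.0), (0.0, -0.5, 8.0)]
        grid = sm.cressman(stations, spec, radii_km=(300.0,))
        # background = mean(4, 8) = 6; symmetric residuals cancel to the mean
        assert grid.values[1, 0] == pytest.approx(6.0, abs=1e-9)

    def test_no_overshoot_away_from_background(self):
        rng = np.random.default_rng(0)
        stations = [
            (100.0 + 4 * rng.uniform(), 30.0 + 4 * rng.uniform(), rng.uniform(0, 30))
            for _ in range(25)
        ]
        grid = sm.cressman(stations, self.SPEC)
        vals = grid.values[~grid.background_only]
        lo = min(s[2] for s in stations)
        hi = max(s[2] for s in stations)
        assert np.all(vals >= lo - 1e-9)
        assert np.all(vals <= hi + 1e-9)

    def test_empty_station_list_rejected(self):
        with pytest.raises(ValueError):
            sm.cressman([], self.SPEC)

    def test_radii_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            sm.cressman([(100.0, 30.0, 1.0)], self.SPEC, radii_km=(100.0, 200.0))

    def test_denser_network_recovers_smooth_field_better(self):
        """Analysis RMSE against a smooth truth drops with station density."""
        spec = sm.GridSpec(lon0=100.0, lat0=30.0, step=0.5, nlon=11, nlat=11)
        truth = lambda lon, lat: 10.0 + 0.8 * (lon - 100.0) - 0.5 * (lat - 30.0)
        rng = np.random.default_rng(3)
        rmses = {}
        for n in (20, 200):
            lons = rng.uniform(100.0, 105.0, n)
            lats = rng.uniform(30.0, 35.0, n)
            grid = sm.cressman(
                list(zip(lons, lats, truth(lons, lats))), spec,
                radii_km=(600.0, 300.0, 150.0),
            )
            lon_g, lat_g = spec.mesh()
            rmses[n] = np.sqrt(np.mean((grid.values - truth(lon_g, lat_g)) ** 2))
        assert rmses[200] < rmses[20]


@pytest.fixture(scope="module")
def quad_model(fixture_tables):
    return fit_ols(gd.to_pairs(fixture_tables["Midnight II"]), degree=2)


class TestPredictSuitability:
    def _uniform_grids(self, tmin, tmax, n=3):
        spec = sm.GridSpec(lon0=100.0, lat0=30.0, step=1.0, nlon=n, nlat=n)
        zeros = np.zeros((n, n))
        return (
            sm.Grid(spec, zeros + tmin),
            sm.Grid(spec, zeros + tmax),
        )

    def test_optimal_regime_scores_high(self, quad_model):
        tmin, tmax = self._uniform_grids(20.0, 30.0)
        smap = sm.predict_suitability(quad_model, tmin, tmax)
        assert np.all(smap.grid.values > 0.5)
        assert not smap.extrapolated.any()

    def test_constant_regime_suppressed(self, quad_model):
        opt = sm.predict_suitability(quad_model, *self._uniform_grids(20.0, 30.0))
        const = sm.predict_suitability(quad_model, *self._uniform_grids(20.0, 20.0))
        assert np.all(const.grid.values < opt.grid.values)

    def test_cold_cells_clamped_and_flagged(self, quad_model):
        smap = sm.predict_suitability(quad_model, *self._uniform_grids(-10.0, -10.0))
        assert smap.extrapolated.all()
        assert np.all(smap.grid.values < 0.1)
        assert smap.provenance["extrapolated_fraction"] == 1.0

    def test_values_in_unit_interval(self, quad_model):
        for t in ((5, 40), (35, 40), (5, 5)):
            smap = sm.predict_suitability(quad_model, *self._uniform_grids(*t))
            assert np.all((smap.grid.values >= 0) & (smap.grid.values <= 1))

    def test_misaligned_grids_rejected(self, quad_model):
        tmin, _ = self._uniform_grids(10, 20, n=3)
        _, tmax = self._uniform_grids(10, 20, n=4)
        with pytest.raises(ValueError, match="aligned"):
            sm.predict_suitability(quad_model, tmin, tmax)


class TestExportMap:
    def _small_map(self):
        spec = sm.GridSpec(lon0=100.0, lat0=30.0, step=1.0, nlon=2, nlat=2)
        grid = sm.Grid(spec, np.array([[0.1, 0.2], [0.3, 0.4]]))
        return sm.SuitabilityMap(
            cultivar="X", month=4, grid=grid,
            extrapolated=np.zeros((2, 2), dtype=bool),
        )

    def test_reexport_byte_identical(self, tmp_path):
        smap = self._small_map()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        sm.export_map(smap, p1)
        sm.export_map(smap, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text().splitlines()[0] == "lon,lat,value,extrapolated"

    def test_empty_grid_rejected(self, tmp_path):
        spec = sm.GridSpec(lon0=0, lat0=0, step=1.0, nlon=1, nlat=1)
        smap = self._small_map()
        smap.grid.values = np.empty((0, 0))
        with pytest.raises(ValueError):
            sm.export_map(smap, tmp_path / "x.csv")

    def test_twelve_monthly_maps(self, tmp_path, fixture_tables):
        model = fit_ols(gd.to_pairs(fixture_tables["Diva"]), degree=2)
        records = sdata.simulate_station_network(30, seed=1)
        clim = sm.monthly_climatology(records)
        spec = sm.GridSpec(lon0=80.0, lat0=20.0, step=2.0, nlon=10, nlat=8)
        for month in range(1, 13):
            sub = clim[clim["month"] == month]
            tmin = sm.cressman(
                sub[["lon", "lat", "tmin_mean_c"]].to_numpy(), spec
            )
            tmax = sm.cressman(
                sub[["lon", "lat", "tmax_mean_c"]].to_numpy(), spec
            )
            smap = sm.predict_suitability(model, tmin, tmax, "Diva", month)
            sm.export_map(smap, tmp_path / f"diva_{month:02d}.csv")
        assert len(list(tmp_path.glob("diva_*.csv"))) == 12
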