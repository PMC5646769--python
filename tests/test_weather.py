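"""Weather decomposition, variogram fitting, kriging, winter summaries."""

import numpy as np
import pandas as pd
import pytest

from biomasstrend import weather
from biomasstrend.weather import (
    CovarianceModel,
    decompose,
    empirical_variogram,
    fit_covariance,
    frost_days,
    great_circle_km,
    krige_daily,
    winter_precip,
)


def make_station_table(rng, n_stations=12, years=(2000, 2001, 2002),
                       alt_span=1000.0, value_fn=None, noise_sd=0.3):
    rows = []
    lons = rng.uniform(6.0, 8.0, n_stations)
    lats = rng.uniform(50.5, 52.0, n_stations)
    alts = np.linspace(0.0, alt_span, n_stations)
    for i in range(n_stations):
        for y in years:
            days = np.arange(365)
            if value_fn is None:
                vals = np.full(365, 5.0)
            else:
                vals = value_fn(y, days, alts[i])
            vals = vals + rng.normal(0, noise_sd, size=365)
            rows.append(
                pd.DataFrame(
                    {
                        "station_id": f"W{i}",
                        "lon": lons[i],
                        "lat": lats[i],
                        "alt": alts[i],
                        "year": y,
                        "day": days,
                        "value": vals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


class TestDecompose:
    def test_constant_series_flat_components(self):
        rng = np.random.default_rng(0)
        df = make_station_table(rng, n_stations=4, noise_sd=0.0)
        dec = decompose(df)
        assert abs(dec.altitude_coef) < 1e-6
        assert np.abs(dec.residuals["residual"]).max() < 1e-6
        det = dec.deterministic([2001], [180], 500.0)
        assert det[0] == pytest.approx(5.0, abs=1e-6)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)

        def fn(y, d, h):
            return 8 + 0.2 * (y - 2001) + 6 * np.sin(2 * np.pi * d / 365) + 0.004 * h

        df = make_station_table(rng, n_stations=6, value_fn=fn)
        dec = decompose(df)
        det = dec.deterministic(
            df["year"].to_numpy(), df["day"].to_numpy(), df["alt"].to_numpy()
        )
        recon = det + dec.residuals["residual"].to_numpy()
        tol = 1e-6 * df["value"].std()
        assert np.abs(recon - df["value"].to_numpy()).max() < tol

    def test_altitude_coefficient_recovery(self):
        rng = np.random.default_rng(2)

        def fn(y, d, h):
            return 8 + 0.3 * (y - 2001) + 5 * np.sin(2 * np.pi * d / 365) + 0.006 * h

        df = make_station_table(rng, value_fn=fn)
        dec = decompose(df)
        assert dec.altitude_coef == pytest.approx(0.006, abs=0.002)

    def test_seasonal_smooth_recovers_sinusoid(self):
        rng = np.random.default_rng(3)
        amp = 7.0

        def fn(y, d, h):
            return 10 + amp * np.cos(2 * np.pi * (d - 200) / 365)

        df = make_station_table(rng, value_fn=fn, alt_span=100.0)
        dec = decompose(df)
        grid = np.arange(365, dtype=float)
        truth = amp * np.cos(2 * np.pi * (grid - 200) / 365)
        r = np.corrcoef(dec.f_t(grid), truth)[0, 1]
        assert r > 0.99

    def test_single_station_rejected(self):
        rng = np.random.default_rng(4)
        df = make_station_table(rng, n_stations=1)
        with pytest.raises(ValueError, match="station"):
            decompose(df)


def simulate_exponential_field(rng, n_stations=100, n_days=60,
                               spatial_range=50.0, temporal_range=2.0, sill=1.0,
                               lon_range=(5.0, 13.0), lat_range=(48.5, 54.0)):
    lon = rng.uniform(*lon_range, n_stations)
    lat = rng.uniform(*lat_range, n_stations)
    h = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    Cs = sill * np.exp(-h / spatial_range)
    Ls = np.linalg.cholesky(Cs + 1e-8 * np.eye(n_stations))
    phi = np.exp(-1.0 / temporal_range)
    Z = rng.normal(size=(n_stations, n_days))
    X = np.empty_like(Z)
    X[:, 0] = Z[:, 0]
    for t in range(1, n_days):
        X[:, t] = phi * X[:, t - 1] + np.sqrt(1 - phi * phi) * Z[:, t]
    field = Ls @ X
    rows = []
    for i in range(n_stations):
        rows.append(
            pd.DataFrame(
                {
                    "station_id": f"W{i}",
                    "lon": lon[i],
                    "lat": lat[i],
                    "alt": 50.0,
                    "year": 2000,
                    "day": np.arange(n_days),
                    "residual": field[i],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCovariance:
    def test_white_noise_is_pure_nugget(self):
        rng = np.random.default_rng(5)
        df = simulate_exponential_field(rng, n_stations=25, n_days=40,
                                        spatial_range=1e-6, temporal_range=1e-6)
        # overwrite with iid noise to make it exactly white; finite-sample
        # variograms keep a small slope, so the assertable property is that
        # the nugget carries (nearly) the whole sill at the true variance
        df["residual"] = rng.normal(0, 1, size=len(df))
        cov = fit_covariance(df)
        assert cov.nugget > 0.8 * cov.sill
        assert cov.nugget == pytest.approx(1.0, rel=0.2)
        if cov.spatial_range > 0:
            # any residual structure is weak at the shortest observed lag
            assert cov.sill - cov.nugget < 0.2 * cov.sill

    def test_spatial_range_recovery(self):
        rng = np.random.default_rng(6)
        df = simulate_exponential_field(rng)
        cov = fit_covariance(df)
        assert abs(cov.spatial_range - 50.0) / 50.0 < 0.5

    def test_sill_recovery(self):
        rng = np.random.default_rng(7)
        df = simulate_exponential_field(rng)
        cov = fit_covariance(df)
        assert cov.sill == pytest.approx(1.0, rel=0.2)

    def test_all_zero_residuals_degenerate(self):
        df = simulate_exponential_field(np.random.default_rng(8), n_stations=5,
                                        n_days=10)
        df["residual"] = 0.0
        cov = fit_covariance(df)
        assert cov.degenerate and cov.sill == 0.0

    def test_variogram_levels_off_at_sill(self):
        rng = np.random.default_rng(9)
        df = simulate_exponential_field(rng)
        vg = empirical_variogram(df)
        far = vg[vg["space_lag_km"] > 150]["gamma"].mean()
        near = vg[vg["space_lag_km"] < 40]["gamma"].mean()
        assert near < far

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CovarianceModel(10.0, 2.0, sill=0.5, nugget=0.8)


@pytest.fixture(scope="module")
def small_network():
    rng = np.random.default_rng(10)

    def fn(y, d, h):
        return 9 + 0.1 * (y - 2000) + 4 * np.sin(2 * np.pi * d / 365) + 0.005 * h

    df = make_station_table(rng, n_stations=6, years=(2000, 2001),
                            value_fn=fn, alt_span=200.0, noise_sd=0.5)
    return df, decompose(df)


class TestKriging:
    def test_exact_at_station_with_zero_nugget(self, small_network):
        df, dec = small_network
        cov = CovarianceModel(spatial_range=60.0, temporal_range=2.0,
                              sill=1.0, nugget=0.0)
        st = df[df["station_id"] == "W2"].iloc[0]
        obs = df[
            (df["station_id"] == "W2") & (df["year"] == 2000) & (df["day"] == 100)
        ]["value"].iloc[0]
        pred = krige_daily(dec, cov, st["lon"], st["lat"], st["alt"],
                           [(2000, 100)])
        assert pred["value"].iloc[0] == pytest.approx(obs, abs=1e-6)

    def test_midpoint_of_equal_valued_stations(self, small_network):
        df, dec = small_network
        # force two stations to share one residual value on one day
        res = dec.residuals
        sel = (res["year"] == 2000) & (res["day"] == 50)
        ids = res[sel]["station_id"].iloc[:2]
        r0 = float(res[sel & (res["station_id"] == ids.iloc[0])]["residual"].iloc[0])
        dec.residuals.loc[sel & res["station_id"].isin(ids), "residual"] = r0
        a = res[sel & (res["station_id"] == ids.iloc[0])].iloc[0]
        b = res[sel & (res["station_id"] == ids.iloc[1])].iloc[0]
        mid_lon, mid_lat = (a["lon"] + b["lon"]) / 2, (a["lat"] + b["lat"]) / 2
        cov = CovarianceModel(60.0, 2.0, sill=1.0, nugget=0.0)
        only_two = dec.residuals[dec.residuals["station_id"].isin(ids)]
        import dataclasses

        dec2 = dataclasses.replace(dec, residuals=only_two)
        pred = krige_daily(dec2, cov, mid_lon, mid_lat, 100.0, [(2000, 50)])
        det = dec.deterministic([2000], [50], 100.0)[0]
        assert pred["value"].iloc[0] == pytest.approx(det + r0, abs=1e-8)

    def test_no_station_within_radius_rejected(self, small_network):
        df, dec = small_network
        cov = CovarianceModel(60.0, 2.0, sill=1.0, nugget=0.1)
        with pytest.raises(ValueError, match="100 km"):
            krige_daily(dec, cov, 20.0, 40.0, 50.0, [(2000, 100)])

    def test_beats_nearest_neighbour_cross_validation(self):
        rng = np.random.default_rng(11)
        field = simulate_exponential_field(
            rng, n_stations=16, n_days=90, spatial_range=80.0,
            lon_range=(6.0, 8.0), lat_range=(50.5, 52.0),
        )
        base = 10.0
        obs = field.rename(columns={"residual": "value"}).copy()
        obs["value"] += base
        alt_map = {f"W{i}": 10.0 + 12.0 * i for i in range(16)}
        obs["alt"] = obs["station_id"].map(alt_map)
        # hold out one station; decompose on the rest needs >= 2 years, so
        # split days into two pseudo-years
        obs["year"] = 2000 + (obs["day"] >= 45).astype(int)
        obs["day"] = obs["day"] % 45
        held = obs[obs["station_id"] == "W0"]
        rest = obs[obs["station_id"] != "W0"]
        dec = decompose(rest)
        cov = fit_covariance(dec.residuals)
        t = held.iloc[0]
        dates = list(zip(held["year"], held["day"]))
        pred = krige_daily(dec, cov, t["lon"], t["lat"], t["alt"], dates)
        krig_rmse = np.sqrt(np.mean((pred["value"].to_numpy() - held["value"].to_numpy()) ** 2))
        # naive oracle: nearest station's raw values
        rest_st = rest.groupby("station_id").first()
        d = great_circle_km(rest_st["lon"].to_numpy(), rest_st["lat"].to_numpy(),
                            t["lon"], t["lat"])
        nn = rest_st.index[np.argmin(d)]
        nn_vals = rest[rest["station_id"] == nn].set_index(["year", "day"])["value"]
        nn_pred = np.array([nn_vals[yd] for yd in dates])
        nn_rmse = np.sqrt(np.mean((nn_pred - held["value"].to_numpy()) ** 2))
        assert krig_rmse < nn_rmse


def _winter_series(temps_by_day):
    rows = [
        {"year": y, "day": d, "value": v} for (y, d), v in temps_by_day.items()
    ]
    return pd.DataFrame(rows)


def _full_winter(season_year, value=5.0):
    d = {}
    for day in range(304, 365):
        d[(season_year - 1, day)] = value
    for day in range(0, 59):
        d[(season_year, day)] = value
    return d


class TestWinterSummaries:
    def test_no_frost_when_warm(self):
        s = _winter_series(_full_winter(2005, value=5.0))
        assert frost_days(s, 2005) == 0

    def test_counts_constructed_subzero_days(self):
        d = _full_winter(2005, value=3.0)
        rng = np.random.default_rng(12)
        keys = list(d)
        frosty = rng.choice(len(keys), size=17, replace=False)
        for i in frosty:
            d[keys[i]] = -2.0
        s = _winter_series(d)
        assert frost_days(s, 2005) == 17
        # brute-force oracle
        assert frost_days(s, 2005) == sum(1 for v in d.values() if v < 0)

    def test_exact_zero_not_frost(self):
        d = _full_winter(2005, value=1.0)
        d[(2004, 310)] = 0.0
        assert frost_days(_winter_series(d), 2005) == 0

    def test_missing_days_listed(self):
        d = _full_winter(2005)
        del d[(2005, 30)]
        with pytest.raises(ValueError, match="missing"):
            frost_days(_winter_series(d), 2005)

    def test_precip_sums(self):
        d = _full_winter(2005, value=1.0)
        s = _winter_series(d)
        assert winter_precip(s, 2005) == pytest.approx(120.0)

    def test_precip_matches_brute_force(self):
        d = _full_winter(2005)
        rng = np.random.default_rng(13)
        for k in d:
            d[k] = float(rng.uniform(0, 10))
        s = _winter_series(d)
        assert winter_precip(s, 2005) == pytest.approx(sum(d.values()))
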