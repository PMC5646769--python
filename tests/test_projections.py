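"""Projection algebra: closed-form declines, seasonal curves, marginal
effects and the no-trend counterfactual."""

import numpy as np
import pytest

from biomasstrend import projections
from biomasstrend.projections import (
    counterfactual_no_trend,
    marginal_effect,
    peak_decline,
    percent_change_from_coef,
    project_draws,
    project_season,
    weighted_decline,
)

from conftest import point_mass_results


class TestPercentChange:
    def test_zero_coefficient(self):
        assert percent_change_from_coef(0.0, 1) == pytest.approx(0.0)

    def test_printed_annual_decline_full_data(self):
        # trend coefficient -0.063 corresponds to a 6.1% annual decline
        assert round(percent_change_from_coef(-0.063, 1), 1) == 6.1

    def test_printed_annual_decline_resampled_subset(self):
        # trend coefficient -0.053 corresponds to a 5.2% annual decline
        assert round(percent_change_from_coef(-0.053, 1), 1) == 5.2

    def test_multi_year_compounding(self):
        one = percent_change_from_coef(-0.1, 1) / 100
        five = percent_change_from_coef(-0.1, 5) / 100
        assert 1 - five == pytest.approx((1 - one) ** 5)


@pytest.fixture(scope="module")
def basic_point_results(small_campaign):
    values = {
        "c": 2.45,
        "log_lambda": -0.063,
        "day": -0.100,
        "day2": -0.447,
        "cluster2": 0.42,
        "cluster3": 0.33,
        "year_x_day": 0.0,
        "year_x_day2": 0.0,
        "sigma_site": 0.0,
        "v": 0.5,
    }
    return point_mass_results(
        small_campaign["samples"], small_campaign["sites"], "basic", values
    )


class TestProjectSeason:
    def test_point_mass_draws_give_deterministic_curve(self, basic_point_results):
        res = basic_point_results
        out = project_season(res, int(res.model.years[0]), window=(120, 240))
        d = res.model.design
        d1, d2 = d.seasonal_profile(np.arange(120, 241))
        y = 2.45 - 0.100 * d1 - 0.447 * d2
        np.testing.assert_allclose(out["mean"].to_numpy(), np.exp(y), rtol=1e-12)
        np.testing.assert_allclose(out["lo_2.5"], out["hi_97.5"], rtol=1e-12)

    def test_negative_quadratic_gives_interior_peak(self, basic_point_results):
        res = basic_point_results
        out = project_season(res, int(res.model.years[0]), window=(90, 302))
        peak = out["mean"].idxmax()
        assert 0 < peak < len(out) - 1

    def test_between_year_ratio_is_trend_factor(self, basic_point_results):
        res = basic_point_results
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        z0 = project_draws(res, y0, window=(150, 160))
        z1 = project_draws(res, y1, window=(150, 160))
        expected = np.exp(-0.063 * (y1 - y0))
        np.testing.assert_allclose(z1 / z0, expected, rtol=1e-12)

    def test_year_outside_fit_rejected(self, basic_point_results):
        with pytest.raises(ValueError, match="outside"):
            project_season(basic_point_results, 1900)


class TestWeightedDecline:
    def test_no_trend_no_decline(self, small_campaign):
        res = point_mass_results(
            small_campaign["samples"], small_campaign["sites"], "basic",
            {"c": 2.0, "log_lambda": 0.0, "day": -0.1, "day2": -0.4, "v": 0.5},
        )
        out = weighted_decline(res, int(res.model.years[0]), int(res.model.years[-1]))
        assert out.decline_percent == pytest.approx(0.0, abs=1e-10)

    def test_equals_closed_form_without_interactions(self, basic_point_results):
        res = basic_point_results
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        out = weighted_decline(res, y0, y1)
        closed = percent_change_from_coef(-0.063, y1 - y0)
        assert out.decline_percent == pytest.approx(closed, rel=1e-12)

    def test_equals_closed_form_per_draw_on_mcmc_fit(self, basic_fit):
        # with year x day interactions numerically zeroed the seasonal sum
        # factorises: the weighted decline equals the closed form for every
        # posterior draw
        res = basic_fit
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        dy = y1 - y0
        names = res.draws.parameter_names
        vals = res.draws.values.copy()
        for p in ("year_x_day", "year_x_day2"):
            vals[:, :, names.index(p)] = 0.0
        from biomasstrend.results import BiomassTrendResults, PosteriorDraws

        d0 = res.draws
        zeroed = BiomassTrendResults(
            res.model,
            PosteriorDraws(vals, names, d0.chains, d0.iterations, d0.burn_in,
                           d0.thin, d0.seed),
        )
        z0 = project_draws(zeroed, y0)
        z1 = project_draws(zeroed, y1)
        ratio = z1.sum(axis=1) / z0.sum(axis=1)
        lam = zeroed.draws.flat("log_lambda")
        np.testing.assert_allclose(ratio, np.exp(lam * dy), rtol=1e-12)

    def test_flattening_peak_weighted_below_peak_decline(self, small_campaign):
        # positive year x day2 flattens the peak over time, so the peak-day
        # decline exceeds the seasonally weighted decline
        res = point_mass_results(
            small_campaign["samples"], small_campaign["sites"], "basic",
            {
                "c": 2.45, "log_lambda": -0.063, "day": -0.1, "day2": -0.447,
                "year_x_day2": 0.010, "v": 0.5,
            },
        )
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        wd = weighted_decline(res, y0, y1)
        pk = peak_decline(res, y0, y1)
        assert wd.decline_percent < pk.decline_percent

    def test_interval_brackets_mean(self, basic_fit):
        y0, y1 = int(basic_fit.model.years[0]), int(basic_fit.model.years[-1])
        out = basic_fit.weighted_decline(y0, y1)
        assert out.interval[0] <= out.decline_percent <= out.interval[1]
        assert out.decline_percent <= 100.0


class TestMarginalEffect:
    def test_no_change_unit_rate(self):
        assert marginal_effect("temperature", 0.5, 0.0).rate == pytest.approx(1.0)

    def test_closed_form(self):
        me = marginal_effect("temperature", 0.5, 0.2)
        assert me.rate == pytest.approx(np.exp(0.1))
        assert me.percent_change == pytest.approx(10.517, abs=0.001)

    def test_declining_arable_with_negative_beta_boosts_biomass(self):
        # arable-land coefficient -1.063 with declining arable cover
        # (delta < 0) yields a rate above one
        me = marginal_effect("arable", -1.063, -0.1)
        assert me.rate > 1.0


class TestCounterfactual:
    def test_flat_trajectories_unit_rate(self, small_campaign):
        cov = small_campaign["covariates"]
        res = point_mass_results(
            small_campaign["samples"], small_campaign["sites"], "basic",
            {"c": 2.0, "log_lambda": -0.063, "day": -0.1, "day2": -0.4, "v": 0.5},
        )
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        rate, (lo, hi) = counterfactual_no_trend(res, {}, y0, y1)
        assert rate == pytest.approx(1.0, abs=1e-12)

    def test_single_covariate_change_equals_marginal_effect(self, small_campaign):
        # a landuse-spec point mass: grassland enters unstandardized, so a
        # shift delta in cover multiplies seasonal totals by exp(beta*delta)
        res = point_mass_results(
            small_campaign["samples"], small_campaign["sites"], "landuse",
            {"c": 2.0, "log_lambda": -0.05, "day": -0.1, "day2": -0.4,
             "grassland": 0.819, "v": 0.5},
            siteyear=small_campaign["covariates"]["siteyear"],
        )
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        delta = -0.15
        rate, _ = counterfactual_no_trend(
            res, {"grassland": (0.5, 0.5 + delta)}, y0, y1
        )
        me = marginal_effect("grassland", 0.819, delta)
        assert rate == pytest.approx(me.rate, rel=1e-12)

    def test_multiple_changes_product_of_marginals(self, small_campaign):
        res = point_mass_results(
            small_campaign["samples"], small_campaign["sites"], "landuse",
            {"c": 2.0, "day": -0.1, "day2": -0.4,
             "grassland": 0.8, "arable": -1.0, "v": 0.5},
            siteyear=small_campaign["covariates"]["siteyear"],
        )
        y0, y1 = int(res.model.years[0]), int(res.model.years[-1])
        rate, _ = counterfactual_no_trend(
            res, {"grassland": (0.5, 0.4), "arable": (0.3, 0.25)}, y0, y1
        )
        expected = marginal_effect("g", 0.8, -0.1).rate * marginal_effect(
            "a", -1.0, -0.05
        ).rate
        assert rate == pytest.approx(expected, rel=1e-12)

    def test_missing_trajectory_for_unknown_covariate_rejected(
        self, basic_point_results
    ):
        y0 = int(basic_point_results.model.years[0])
        y1 = int(basic_point_results.model.years[-1])
        with pytest.raises(ValueError, match="not in the model"):
            counterfactual_no_trend(
                basic_point_results, {"soil_ph": (5.0, 6.0)}, y0, y1
            )
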