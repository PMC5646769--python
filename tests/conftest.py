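"""Shared fixtures: small synthetic campaigns and reusable MCMC fits."""

import numpy as np
import pandas as pd
import pytest

from biomasstrend.model import BiomassTrendModel
from biomasstrend.simulate import GeneratorConfig, TruthParams, generate_dataset

BASIC_TRUTH_COEFS = {
    "day": -0.100,
    "day2": -0.447,
    "cluster2": 0.420,
    "cluster3": 0.332,
}


def make_campaign(
    n_sites=15,
    n_site_years=22,
    years=tuple(range(1995, 2011)),
    log_lambda=-0.063,
    sigma_site=0.334,
    v=0.870,
    seed=7,
    coefficients=None,
):
    truth = TruthParams(
        c=2.450,
        log_lambda=log_lambda,
        coefficients=dict(coefficients or BASIC_TRUTH_COEFS),
        sigma_site=sigma_site,
        v=v,
    )
    cfg = GeneratorConfig(
        n_sites=n_sites,
        n_site_years=n_site_years,
        years=years,
        truth=truth,
        seed=seed,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_campaign():
    """Trended synthetic campaign: 15 sites, 22 site-years, 16 years."""
    cfg, (samples, sites, cov, truth) = make_campaign()
    return {
        "config": cfg,
        "samples": samples,
        "sites": sites,
        "covariates": cov,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def basic_fit(small_campaign):
    """Basic-spec fit of the small trended campaign (shared across tests)."""
    model = BiomassTrendModel(
        small_campaign["samples"], small_campaign["sites"], spec="basic"
    )
    return model.fit(seed=11, chains=3, iterations=6000, burn_in=1500, thin=5)


@pytest.fixture(scope="session")
def null_fit(small_campaign):
    """Null-spec (no trend) fit of the same trended campaign."""
    model = BiomassTrendModel(
        small_campaign["samples"], small_campaign["sites"], spec="null"
    )
    return model.fit(seed=12, chains=3, iterations=4000, burn_in=1000, thin=4)


def point_mass_results(samples, sites, spec, values, daily=None, siteyear=None):
    """Results object whose posterior is a point mass at ``values``.

    ``values`` maps parameter names (c, log_lambda, design columns,
    sigma_site, v) to scalars; unset parameters default to zero.  Useful for
    checking projection algebra against closed forms.
    """
    from biomasstrend.results import BiomassTrendResults, PosteriorDraws

    model = BiomassTrendModel(
        samples, sites, spec=spec,
        daily_covariates=daily, siteyear_covariates=siteyear,
    )
    d = model.design
    names = (
        ["c"]
        + (["log_lambda"] if model.spec.include_year else [])
        + list(d.columns)
        + [f"u[{s}]" for s in d.site_ids]
        + ["sigma_site", "v", "deviance"]
    )
    row = np.array([float(values.get(n, 0.0)) for n in names])
    vals = np.tile(row, (2, 50, 1))
    draws = PosteriorDraws(
        values=vals, parameter_names=names, chains=2,
        iterations=50, burn_in=0, thin=1, seed=0,
    )
    return BiomassTrendResults(model, draws)


@pytest.fixture(scope="session")
def tiny_samples():
    return pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "site_id": ["s1", "s1", "s2"],
            "year": [2000, 2000, 2001],
            "tau1": [100, 111, 100],
            "tau2": [110, 120, 109],
            "mass_g": [1.0, 2.0, 3.0],
        }
    )


@pytest.fixture(scope="session")
def tiny_sites():
    return pd.DataFrame(
        {
            "site_id": ["s1", "s2"],
            "cluster": [1, 2],
            "lon": [6.5, 6.8],
            "lat": [51.0, 51.2],
            "alt": [40.0, 60.0],
        }
    )
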