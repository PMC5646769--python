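"""Latent daily log-normal biomass model for interval-aggregated catches.

A trap catch accumulated over an inclusive exposure interval [tau1, tau2] is
modelled as normally distributed about the sum of latent expected daily
biomass values::

    m_j ~ Normal(mu_j, sigma2_j)
    mu_j = sum_t z_t,          z_t = exp(y_t)
    y_t  = c + log_lambda * k + x_t' beta + u_s
    sigma2_j = sum_t sigma2_t, sigma2_t = exp(2 y_t + v) (exp(v) - 1)

where ``k`` is the year index, ``u_s ~ Normal(0, sigma2_site)`` a site random
intercept and ``v`` the residual variance of daily log-biomass (so sigma2_t
is the exact method-of-moments variance of a log-normal with log-mean y and
log-variance v).  Summing on the natural scale — rather than modelling log
total mass — is what makes unequal exposure intervals commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import _validate_samples

DAILY_COVARIATES = ["temperature", "precipitation", "wind"]
SITEYEAR_COVARIATES = [
    "frost_days",
    "winter_precip",
    "arable",
    "grassland",
    "forest",
    "water",
    "herb_richness",
    "tree_richness",
    "ell_nitrogen",
    "ell_ph",
    "ell_light",
    "ell_temperature",
    "ell_moisture",
]
LANDUSE_FRACTIONS = ["arable", "grassland", "forest", "water"]

# Columns never standardized: indicator dummies, land-use fractions (already
# on a bounded 0-1 scale) and interaction products of such columns.
_UNSTANDARDIZED = {"cluster2", "cluster3", *LANDUSE_FRACTIONS}


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate columns (besides intercept and year trend) enter X.

    ``columns`` lists the beta columns in order; ``include_year`` switches
    the annual trend term log_lambda * k on or off.  Interaction columns are
    named ``year_x_<col>`` and are built as the product of the raw year index
    with the (standardized where applicable) component column.
    """

    name: str
    columns: tuple[str, ...]
    include_year: bool = True

    @property
    def n_parameters(self) -> int:
        """Location parameters: intercept + trend (if any) + betas."""
        return 1 + int(self.include_year) + len(self.columns)


_BASE = ("day", "day2", "cluster2", "cluster3")
_BASIC = _BASE + ("year_x_day", "year_x_day2")

SPEC_PRESETS: dict[str, ModelSpec] = {
    "null": ModelSpec("null", _BASE, include_year=False),
    "basic": ModelSpec("basic", _BASIC),
    "weather": ModelSpec(
        "weather",
        _BASIC + ("temperature", "precipitation", "wind", "frost_days", "winter_precip"),
    ),
    "habitat": ModelSpec(
        "habitat",
        _BASIC
        + (
            "herb_richness",
            "tree_richness",
            "ell_nitrogen",
            "ell_ph",
            "ell_moisture",
            "ell_light",
            "ell_temperature",
        ),
    ),
    "landuse": ModelSpec("landuse", _BASIC + tuple(LANDUSE_FRACTIONS)),
    "landuse_interactions": ModelSpec(
        "landuse_interactions",
        _BASIC
        + tuple(LANDUSE_FRACTIONS)
        + ("year_x_arable", "year_x_forest", "year_x_water", "year_x_grassland"),
    ),
    "final": ModelSpec(
        "final",
        (
            "day",
            "day2",
            "cluster2",
            "cluster3",
            "temperature",
            "precipitation",
            "frost_days",
            "arable",
            "forest",
            "grassland",
            "water",
            "herb_richness",
            "tree_richness",
            "ell_nitrogen",
            "ell_light",
            "ell_temperature",
            "year_x_day",
            "year_x_day2",
            "year_x_arable",
            "year_x_forest",
            "year_x_grassland",
        ),
    ),
}


def get_spec(spec: str | ModelSpec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return SPEC_PRESETS[spec]
    except KeyError:
        raise ValueError(
            f"unknown model spec {spec!r}; choose from {sorted(SPEC_PRESETS)}"
        ) from None


@dataclass
class ModelParams:
    """Parameter vector of the observation model (log-scale throughout)."""

    c: float
    log_lambda: float
    beta: np.ndarray
    u: np.ndarray
    sigma2_site: float
    v: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.sigma2_site < 0:
            raise ValueError("sigma2_site must be non-negative")
        if self.v < 0:
            raise ValueError("v must be non-negative")


@dataclass
class DesignMatrix:
    """Day-level design for the beta columns, plus bookkeeping.

    One row per exposure day of every sample.  ``sample_starts`` gives the
    offset of each sample's first day-row (rows of one sample are
    contiguous); ``site_index``/``year_k`` are per-row; ``standardization``
    records the (mean, sd) applied to each standardized column so the same
    transform can be replayed on new covariate values.
    """

    X: np.ndarray
    columns: list[str]
    year_k: np.ndarray
    site_index: np.ndarray
    sample_starts: np.ndarray
    sample_site: np.ndarray
    day_of_year: np.ndarray
    site_ids: list[str]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_starts)

    def standardize_value(self, column: str, raw: np.ndarray) -> np.ndarray:
        """Apply the stored (mean, sd) transform of ``column`` to new values."""
        if column not in self.standardization:
            return np.asarray(raw, dtype=float)
        m, s = self.standardization[column]
        return (np.asarray(raw, dtype=float) - m) / s

    def seasonal_profile(self, days: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(day, day2) design values for arbitrary days of year.

        ``day2`` is the standardized square of the standardized day number,
        replaying exactly the transform used at build time.
        """
        d1 = self.standardize_value("day", np.asarray(days, dtype=float))
        return d1, self.standardize_value("day2", d1**2)


def _standardize(col: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = float(col.mean())
    s = float(col.std(ddof=0))
    if s == 0:
        raise ValueError("cannot standardize a constant column")
    return (col - m) / s, m, s


def build_design(
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    spec: str | ModelSpec,
    daily_covariates: pd.DataFrame | None = None,
    siteyear_covariates: pd.DataFrame | None = None,
    year_coding: str = "offset",
) -> DesignMatrix:
    """Expand samples to day-level rows and assemble the standardized design.

    Day-number and day-number^2 columns are built from the day of year and
    standardized; external covariates are merged by (site_id, year, day) or
    (site_id, year) and standardized, except land-use fractions which stay on
    their raw [0, 1] scale.  The year index is exempt from standardization:
    with ``year_coding="offset"`` (default) it is ``year - min(year)``, with
    ``"consecutive"`` the rank of the year among the years present (earliest
    year -> 0).
    """
    spec = get_spec(spec)
    samples = _validate_samples(samples).sort_values(
        ["site_id", "year", "tau1"], kind="mergesort"
    )
    site_ids = sorted(sites["site_id"].astype(str))
    site_pos = {s: i for i, s in enumerate(site_ids)}
    unknown = set(samples["site_id"]) - set(site_ids)
    if unknown:
        raise ValueError(f"samples reference unknown site(s): {sorted(unknown)[:5]}")
    cluster = dict(zip(sites["site_id"].astype(str), sites["cluster"].astype(int)))

    years = np.sort(samples["year"].unique())
    if year_coding == "offset":
        year_index = {int(y): int(y - years[0]) for y in years}
    elif year_coding == "consecutive":
        year_index = {int(y): i for i, y in enumerate(years)}
    else:
        raise ValueError("year_coding must be 'offset' or 'consecutive'")

    tau1 = samples["tau1"].to_numpy()
    tau2 = samples["tau2"].to_numpy()
    n_days = tau2 - tau1 + 1
    starts = np.concatenate([[0], np.cumsum(n_days)[:-1]])
    total = int(n_days.sum())

    day = np.concatenate([np.arange(a, b + 1) for a, b in zip(tau1, tau2)])
    row_sample = np.repeat(np.arange(len(samples)), n_days)
    sample_site = samples["site_id"].map(site_pos).to_numpy()
    row_site = sample_site[row_sample]
    row_year = samples["year"].to_numpy()[row_sample]
    year_k = np.array([year_index[int(y)] for y in row_year], dtype=float)

    # day2 is the square of the *standardized* day number (then itself
    # standardized), so a negative day2 coefficient gives a dome-shaped
    # season peaking near the mean sampling day
    day_std, day_m, day_s = _standardize(day.astype(float))
    raw: dict[str, np.ndarray] = {
        "day": day.astype(float),
        "day2": day_std**2,
        "cluster2": np.array(
            [1.0 if cluster[site_ids[i]] == 2 else 0.0 for i in row_site]
        ),
        "cluster3": np.array(
            [1.0 if cluster[site_ids[i]] == 3 else 0.0 for i in row_site]
        ),
    }

    needed = set()
    for col in spec.columns:
        base = col[len("year_x_"):] if col.startswith("year_x_") else col
        needed.add(base)

    ext_daily = needed & set(DAILY_COVARIATES)
    if ext_daily:
        if daily_covariates is None:
            raise ValueError(
                f"spec {spec.name!r} requires daily covariates {sorted(ext_daily)}"
            )
        key = pd.DataFrame(
            {
                "site_id": [site_ids[i] for i in row_site],
                "year": row_year,
                "day": day,
            }
        )
        merged = key.merge(
            daily_covariates, on=["site_id", "year", "day"], how="left", sort=False
        )
        for c in sorted(ext_daily):
            if c not in merged.columns:
                raise ValueError(f"daily covariate table lacks column {c!r}")
            vals = merged[c].to_numpy(dtype=float)
            if np.isnan(vals).any():
                i = int(np.argmax(np.isnan(vals)))
                raise ValueError(
                    f"missing daily covariate {c!r} for site "
                    f"{site_ids[row_site[i]]}, year {row_year[i]}, day {day[i]}"
                )
            raw[c] = vals

    ext_sy = needed & set(SITEYEAR_COVARIATES)
    if ext_sy:
        if siteyear_covariates is None:
            raise ValueError(
                f"spec {spec.name!r} requires site-year covariates {sorted(ext_sy)}"
            )
        key = pd.DataFrame(
            {"site_id": [site_ids[i] for i in row_site], "year": row_year}
        )
        merged = key.merge(
            siteyear_covariates, on=["site_id", "year"], how="left", sort=False
        )
        for c in sorted(ext_sy):
            if c not in merged.columns:
                raise ValueError(f"site-year covariate table lacks column {c!r}")
            vals = merged[c].to_numpy(dtype=float)
            if np.isnan(vals).any():
                i = int(np.argmax(np.isnan(vals)))
                raise ValueError(
                    f"missing site-year covariate {c!r} for site "
                    f"{site_ids[row_site[i]]}, year {row_year[i]}"
                )
            raw[c] = vals

    leftover = needed - set(raw)
    if leftover:
        raise ValueError(f"spec requires unknown covariate(s): {sorted(leftover)}")

    standardization: dict[str, tuple[float, float]] = {}
    cols: dict[str, np.ndarray] = {}
    for name, vals in raw.items():
        if name in _UNSTANDARDIZED:
            cols[name] = vals
        else:
            z, m, s = _standardize(vals)
            cols[name] = z
            standardization[name] = (m, s)

    X = np.empty((total, len(spec.columns)))
    for j, col in enumerate(spec.columns):
        if col.startswith("year_x_"):
            X[:, j] = year_k * cols[col[len("year_x_"):]]
        else:
            X[:, j] = cols[col]

    return DesignMatrix(
        X=X,
        columns=list(spec.columns),
        year_k=year_k if spec.include_year else np.zeros(total),
        site_index=row_site,
        sample_starts=starts,
        sample_site=sample_site,
        day_of_year=day,
        site_ids=site_ids,
        standardization=standardization,
    )


# ---------------------------------------------------------------------------
# Elementary model operations (vectorized over days)


def daily_log_mean(
    c: float,
    log_lambda: float,
    year_index,
    x,
    beta,
    u_site,
) -> np.ndarray:
    """Linear predictor y = c + log_lambda * k + x' beta + u_s (log g/day)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if x.shape[1] != beta.shape[0]:
        raise ValueError(
            f"covariate row width {x.shape[1]} != coefficient length {beta.shape[0]}"
        )
    return c + log_lambda * np.asarray(year_index, dtype=float) + x @ beta + u_site


def daily_variance(y, v: float) -> np.ndarray:
    """Variance of daily biomass: exp(2y + v) (exp(v) - 1).

    This is the exact variance of a log-normal variate with log-mean ``y``
    and log-variance ``v``, so residual spread is parameterized on the same
    log scale as the site random effect.
    """
    if v < 0:
        raise ValueError("v must be non-negative")
    return np.exp(2.0 * np.asarray(y, dtype=float) + v) * np.expm1(v)


def sample_moments(y_days: np.ndarray, v: float) -> tuple[float, float]:
    """Aggregate (mu_j, sigma2_j) over one sample's exposure days."""
    z = np.exp(np.asarray(y_days, dtype=float))
    return float(z.sum()), float(daily_variance(y_days, v).sum())


def _eta(design: DesignMatrix, params: ModelParams) -> np.ndarray:
    if len(params.beta) != len(design.columns):
        raise ValueError(
            f"beta length {len(params.beta)} != design width {len(design.columns)}"
        )
    if len(params.u) != len(design.site_ids):
        raise ValueError("u length does not match number of sites")
    return (
        params.c
        + params.log_lambda * design.year_k
        + design.X @ params.beta
        + params.u[design.site_index]
    )


def aggregate_moments(
    design: DesignMatrix, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (mu_j, sigma2_j) under the model, vectorized."""
    eta = _eta(design, params)
    z = np.exp(eta)
    mu = np.add.reduceat(z, design.sample_starts)
    s2 = np.exp(params.v) * np.expm1(params.v) * np.add.reduceat(z * z, design.sample_starts)
    return mu, s2


def log_likelihood(
    design: DesignMatrix, params: ModelParams, mass_g: np.ndarray
) -> float:
    """Sum of normal log-densities of the catches at their model moments."""
    mu, s2 = aggregate_moments(design, params)
    if np.any(s2 <= 0):
        j = int(np.argmax(s2 <= 0))
        raise ValueError(f"non-positive aggregate variance for sample index {j}")
    m = np.asarray(mass_g, dtype=float)
    ll = -0.5 * np.sum(np.log(2.0 * np.pi * s2) + (m - mu) ** 2 / s2)
    if not np.isfinite(ll):
        j = int(np.argmax(~np.isfinite(np.log(s2) + (m - mu) ** 2 / s2)))
        raise ValueError(f"non-finite log-likelihood at sample index {j}")
    return float(ll)


class BiomassTrendModel:
    """Interval-aggregated biomass trend model bound to a dataset.

    Parameters
    ----------
    samples : DataFrame
        Trap catches (sample_id, site_id, year, tau1, tau2, mass_g).
    sites : DataFrame
        Site table (site_id, cluster, lon, lat, alt).
    spec : str or ModelSpec
        Covariate set; one of the named presets (``"null"``, ``"basic"``,
        ``"weather"``, ``"habitat"``, ``"landuse"``,
        ``"landuse_interactions"``, ``"final"``) or a custom ModelSpec.
    daily_covariates, siteyear_covariates : DataFrame, optional
        External covariate tables, required only when the spec uses them.
    year_coding : str
        ``"offset"`` (calendar offset from the first year, default) or
        ``"consecutive"`` (rank of the year among observed years).

    Examples
    --------
    >>> model = BiomassTrendModel(samples, sites, spec="basic")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        sites: pd.DataFrame,
        spec: str | ModelSpec = "basic",
        daily_covariates: pd.DataFrame | None = None,
        siteyear_covariates: pd.DataFrame | None = None,
        year_coding: str = "offset",
    ) -> None:
        self.spec = get_spec(spec)
        self.samples = _validate_samples(samples).sort_values(
            ["site_id", "year", "tau1"], kind="mergesort"
        )
        self.sites = sites
        self.year_coding = year_coding
        self.design = build_design(
            self.samples,
            sites,
            self.spec,
            daily_covariates=daily_covariates,
            siteyear_covariates=siteyear_covariates,
            year_coding=year_coding,
        )
        self.mass_g = self.samples["mass_g"].to_numpy(dtype=float)
        self.years = np.sort(self.samples["year"].unique())

    @classmethod
    def from_csv(
        cls,
        samples_path,
        sites_path,
        spec: str | ModelSpec = "basic",
        daily_covariates_path=None,
        siteyear_covariates_path=None,
        **kwargs,
    ) -> "BiomassTrendModel":
        from . import io

        return cls(
            io.read_samples(samples_path),
            io.read_sites(sites_path),
            spec=spec,
            daily_covariates=(
                io.read_daily_covariates(daily_covariates_path)
                if daily_covariates_path
                else None
            ),
            siteyear_covariates=(
                io.read_siteyear_covariates(siteyear_covariates_path)
                if siteyear_covariates_path
                else None
            ),
            **kwargs,
        )

    def log_likelihood(self, params: ModelParams) -> float:
        return log_likelihood(self.design, params, self.mass_g)

    def fit(
        self,
        seed: int,
        chains: int = 3,
        iterations: int = 6000,
        burn_in: int = 1000,
        thin: int = 5,
        progress: bool = False,
    ):
        """Fit by adaptive Metropolis-within-Gibbs MCMC.

        The default run length (3 chains x 6000 iterations, 1000 burn-in,
        thin 5) is a desk-scale protocol; pass ``iterations=24000,
        burn_in=4000, thin=10`` for the full production protocol.  Proposal
        scales adapt during burn-in only, so the retained chain targets the
        exact posterior.
        """
        from .sampler import run_chains

        return run_chains(
            self,
            seed=seed,
            chains=chains,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            progress=progress,
        )
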