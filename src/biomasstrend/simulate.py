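"""Synthetic trap-campaign generator with known ground truth.

Emulates a multi-year malaise-trap monitoring campaign: a network of sites
in a lowland box, each sampled in one or a few seasons; contiguous exposure
intervals (truncated-normal lengths, configurable mean/sd) tiling each
site-year's trapping window; seasonal weather with AR(1) day-to-day noise;
land-use fractions from a Dirichlet; plant-survey covariates around cluster
means.  Catch masses are drawn from the same observation model the fitting
module uses — normal about the summed latent daily log-normal biomass — and
clipped at zero (the model's normal tail admits negative masses; the clipped
fraction is recorded in the truth record).

The generator is deterministic given (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, ModelParams, build_design, aggregate_moments

#: Default truth coefficients on the standardized-design scale (the scale the
#: fitting module reports): intercept ~2.45 log g/day, ~8% annual decline, a
#: dome-shaped season, modest cluster contrasts and weather effects.
DEFAULT_TRUTH_COEFFICIENTS = {
    "day": -0.100,
    "day2": -0.447,
    "cluster2": 0.420,
    "cluster3": 0.332,
    "temperature": 0.304,
    "precipitation": -0.071,
    "year_x_day": -0.003,
    "year_x_day2": 0.010,
}


@dataclass
class TruthParams:
    """Ground-truth parameter values used by the forward model."""

    c: float = 2.450
    log_lambda: float = -0.080
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_COEFFICIENTS)
    )
    sigma_site: float = 0.334
    v: float = 0.870

    def __post_init__(self) -> None:
        if self.sigma_site < 0 or self.v < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic campaign.

    Defaults mirror the reference campaign: 63 sites / 96 site-years over
    1989-2016, traps emptied on average every 11.2 days (sd 6.3), season
    March-October (days 59-303, Jan 1 = 0), habitat clusters in 19:41:3
    proportions.
    """

    n_sites: int = 63
    n_site_years: int = 96
    years: tuple[int, ...] = tuple(range(1989, 2017))
    cluster_probabilities: tuple[float, float, float] = (19 / 63, 41 / 63, 3 / 63)
    season_window: tuple[int, int] = (59, 303)
    window_jitter_days: int = 60
    interval_mean_days: float = 11.2
    interval_sd_days: float = 6.3
    max_years_per_site: int = 4
    truth: TruthParams = field(default_factory=TruthParams)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.cluster_probabilities, dtype=float)
        if p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ValueError("cluster_probabilities must be a 3-simplex")
        if self.interval_mean_days <= 0:
            raise ValueError("interval_mean_days must be positive")
        w0, w1 = self.season_window
        if not (0 <= w0 < w1 <= 365):
            raise ValueError("season_window must lie within one year")
        if self.n_site_years < self.n_sites:
            raise ValueError("n_site_years must be at least n_sites")


@dataclass
class TruthRecord:
    """Everything needed to score recovery against the generating process."""

    params: TruthParams
    u: dict[str, float]
    mu: dict[str, float]
    sigma2: dict[str, float]
    clipped_fraction: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "params": asdict(self.params),
            "u": self.u,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "clipped_fraction": self.clipped_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            params=TruthParams(**d["params"]),
            u=d["u"],
            mu=d["mu"],
            sigma2=d["sigma2"],
            clipped_fraction=d["clipped_fraction"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# sites and schedules


def generate_sites(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the trap network: clusters, lowland coordinates, low-relief altitude."""
    if config.n_sites < 1:
        raise ValueError("need at least one site")
    n = config.n_sites
    width = len(str(n))
    clusters = rng.choice([1, 2, 3], size=n, p=config.cluster_probabilities)
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "cluster": clusters,
            "lon": rng.uniform(6.0, 7.5, size=n),
            "lat": rng.uniform(50.7, 52.0, size=n),
            "alt": rng.uniform(20.0, 120.0, size=n),
        }
    )


def _truncnorm_parent_moments(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a normal truncated at 1 whose truncated
    distribution has the requested mean and sd."""
    if sd == 0:
        return mean, 0.0

    def eqs(x):
        mu, ls = x
        sig = np.exp(ls)
        a = (1.0 - mu) / sig
        m, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(var) - sd]

    sol = optimize.fsolve(eqs, [mean, np.log(sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def generate_exposure_schedule(
    config: GeneratorConfig,
    rng: np.random.Generator,
    window: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Contiguous exposure intervals tiling a trapping window.

    Interval lengths are integer-rounded draws from a normal truncated at 1
    day whose parent parameters are moment-matched so the truncated law has
    the configured mean/sd.  The last interval is cut at the window end; a
    window shorter than one draw yields a single interval covering it.
    """
    w0, w1 = window if window is not None else config.season_window
    if w1 < w0:
        raise ValueError("empty trapping window")
    mu, sig = _truncnorm_parent_moments(
        config.interval_mean_days, config.interval_sd_days
    )
    intervals: list[tuple[int, int]] = []
    t = w0
    while t <= w1:
        if sig == 0:
            length = max(1, int(round(mu)))
        else:
            draw = rng.normal(mu, sig)
            while draw < 1.0:
                draw = rng.normal(mu, sig)
            length = int(round(draw))
        end = min(t + length - 1, w1)
        intervals.append((t, end))
        t = end + 1
    return intervals


def _assign_site_years(config: GeneratorConfig, rng: np.random.Generator,
                       site_ids: list[str]) -> pd.DataFrame:
    """Give every site one sampling year; spread the remaining site-years
    over randomly chosen sites (resampling, capped per site)."""
    n_extra = config.n_site_years - config.n_sites
    counts = {s: 1 for s in site_ids}
    eligible = list(site_ids)
    for _ in range(n_extra):
        if not eligible:
            raise ValueError("cannot place all site-years under the per-site cap")
        s = eligible[rng.integers(len(eligible))]
        counts[s] += 1
        if counts[s] >= config.max_years_per_site:
            eligible.remove(s)
    rows = []
    years = np.asarray(config.years)
    for s in site_ids:
        ys = rng.choice(years, size=counts[s], replace=False)
        for y in np.sort(ys):
            rows.append({"site_id": s, "year": int(y)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariates


def _seasonal_ar1(rng, days: np.ndarray, base: float, amplitude: float,
                  peak_day: float, noise_sd: float, phi: float = 0.7) -> np.ndarray:
    seasonal = base + amplitude * np.cos(2.0 * np.pi * (days - peak_day) / 365.0)
    e = np.empty(len(days))
    e[0] = rng.normal(0, noise_sd)
    innov_sd = noise_sd * np.sqrt(1.0 - phi * phi)
    for i in range(1, len(days)):
        e[i] = phi * e[i - 1] + rng.normal(0, innov_sd)
    return seasonal + e


_ELLENBERG_CLUSTER_MEANS = {
    # nutrient-poor (1), nutrient-rich (2), pioneer/shrub (3)
    "ell_nitrogen": (3.5, 6.5, 5.0),
    "ell_ph": (4.5, 6.5, 6.0),
    "ell_light": (7.5, 7.0, 6.5),
    "ell_temperature": (5.5, 5.8, 5.7),
    "ell_moisture": (4.5, 5.5, 5.0),
}


def _generate_covariates(
    config: GeneratorConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame,
    site_years: pd.DataFrame,
    windows: dict[tuple[str, int], tuple[int, int]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cluster = dict(zip(sites["site_id"], sites["cluster"]))
    y0 = min(config.years)

    daily_rows = []
    for _, r in site_years.iterrows():
        w0, w1 = windows[(r["site_id"], r["year"])]
        days = np.arange(w0, w1 + 1)
        temp = _seasonal_ar1(rng, days, base=10.0, amplitude=-8.0,
                             peak_day=15.0, noise_sd=2.0)
        precip = np.clip(
            _seasonal_ar1(rng, days, base=2.0, amplitude=0.5,
                          peak_day=200.0, noise_sd=1.5, phi=0.3),
            0.0, None,
        )
        wind = np.clip(
            _seasonal_ar1(rng, days, base=3.0, amplitude=0.8,
                          peak_day=15.0, noise_sd=0.8, phi=0.5),
            0.0, None,
        )
        daily_rows.append(
            pd.DataFrame(
                {
                    "site_id": r["site_id"],
                    "year": r["year"],
                    "day": days,
                    "temperature": temp,
                    "precipitation": precip,
                    "wind": wind,
                }
            )
        )
    daily = pd.concat(daily_rows, ignore_index=True)

    # site-level land use at two epochs, logit-interpolated per sampling year
    from .habitat import interpolate_cover

    landuse_e1 = {}
    landuse_e2 = {}
    for s in sites["site_id"]:
        fr1 = rng.dirichlet([2.0, 2.0, 2.0, 0.5, 1.0])  # arable forest grass water other
        shift = rng.normal([-0.4, 0.3, 0.0, 0.0], 0.2)
        logit = lambda p: np.log(p / (1.0 - p))
        inv = lambda x: 1.0 / (1.0 + np.exp(-x))
        fr2 = inv(logit(np.clip(fr1[:4], 1e-4, 1 - 1e-4)) + shift)
        landuse_e1[s] = fr1[:4]
        landuse_e2[s] = fr2

    sy_rows = []
    for _, r in site_years.iterrows():
        s, y = r["site_id"], r["year"]
        cl = cluster[s]
        with warnings.catch_warnings():
            # sampling years slightly outside the two survey epochs are
            # expected here; extrapolation is intended
            warnings.simplefilter("ignore", UserWarning)
            lu = [
                interpolate_cover(
                    float(np.clip(landuse_e1[s][i], 1e-4, 1 - 1e-4)),
                    1991,
                    float(np.clip(landuse_e2[s][i], 1e-4, 1 - 1e-4)),
                    2013,
                    y,
                )
                for i in range(4)
            ]
        row = {
            "site_id": s,
            "year": y,
            "frost_days": int(rng.poisson(30)),
            "winter_precip": float(max(0.0, rng.normal(250.0, 50.0))),
            "arable": lu[0],
            "forest": lu[1],
            "grassland": lu[2],
            "water": lu[3],
            "herb_richness": int(rng.poisson(np.exp(3.4 - 0.034 * (y - y0)))),
            "tree_richness": int(rng.poisson(np.exp(1.6 - 0.01 * (y - y0)))),
            "shrub_richness": int(rng.poisson(np.exp(1.3 - 0.01 * (y - y0)))),
        }
        for name, means in _ELLENBERG_CLUSTER_MEANS.items():
            row[name] = float(np.clip(rng.normal(means[cl - 1], 0.4), 1.0, 9.0))
        sy_rows.append(row)
    siteyear = pd.DataFrame(sy_rows)
    return daily, siteyear


# ---------------------------------------------------------------------------
# full dataset


def _spec_from_truth(truth: TruthParams) -> ModelSpec:
    return ModelSpec("truth", tuple(truth.coefficients), include_year=True)


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], TruthRecord]:
    """Generate (samples, sites, covariates, truth) from the forward model.

    ``covariates`` is a dict with ``"daily"`` and ``"siteyear"`` tables in
    the schemas the fitting module consumes.  The truth coefficients apply
    to the standardized design built from the generated data itself, so a
    refit on the output recovers them on the same scale.
    """
    config = config or GeneratorConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    sites = generate_sites(config, rng)
    site_years = _assign_site_years(config, rng, list(sites["site_id"]))

    w0, w1 = config.season_window
    jit = min(config.window_jitter_days, (w1 - w0) // 3)
    windows = {}
    sample_rows = []
    for _, r in site_years.iterrows():
        a = int(rng.integers(w0, w0 + jit + 1))
        b = int(rng.integers(w1 - jit, w1 + 1))
        windows[(r["site_id"], r["year"])] = (a, b)
        for tau1, tau2 in generate_exposure_schedule(config, rng, (a, b)):
            sample_rows.append(
                {
                    "site_id": r["site_id"],
                    "year": r["year"],
                    "tau1": tau1,
                    "tau2": tau2,
                }
            )
    samples = pd.DataFrame(sample_rows).sort_values(
        ["site_id", "year", "tau1"], kind="mergesort", ignore_index=True
    )
    samples.insert(0, "sample_id", [f"J{i + 1:05d}" for i in range(len(samples))])
    samples["mass_g"] = 0.0  # placeholder for design construction

    daily, siteyear = _generate_covariates(config, rng, sites, site_years, windows)

    truth = config.truth
    spec = _spec_from_truth(truth)
    design = build_design(
        samples,
        sites,
        spec,
        daily_covariates=daily,
        siteyear_covariates=siteyear,
        year_coding="offset",
    )
    u = rng.normal(0.0, truth.sigma_site, size=len(design.site_ids))
    params = ModelParams(
        c=truth.c,
        log_lambda=truth.log_lambda,
        beta=np.array([truth.coefficients[c] for c in design.columns]),
        u=u,
        sigma2_site=truth.sigma_site**2,
        v=truth.v,
    )
    mu, sigma2 = aggregate_moments(design, params)
    raw = rng.normal(mu, np.sqrt(sigma2))
    clipped = raw < 0
    samples["mass_g"] = np.where(clipped, 0.0, raw)

    record = TruthRecord(
        params=truth,
        u={s: float(val) for s, val in zip(design.site_ids, u)},
        mu={sid: float(m) for sid, m in zip(samples["sample_id"], mu)},
        sigma2={sid: float(s2) for sid, s2 in zip(samples["sample_id"], sigma2)},
        clipped_fraction=float(clipped.mean()),
        seed=seed,
    )
    return samples, sites, {"daily": daily, "siteyear": siteyear}, record
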