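"""Tabular input/output and schema validation.

All on-disk formats are plain CSV (comma-separated, UTF-8, header row
required).  Dates are stored as a calendar year plus an integer day-of-year
with January 1 = day 0.  Exposure intervals are stored with both endpoints
inclusive, so a one-day catch has ``tau1 == tau2`` and exposure length
``tau2 - tau1 + 1 == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or a file is malformed."""


class ValidationError(ValueError):
    """A row violates an invariant (negative mass, reversed interval, ...)."""


SAMPLE_COLUMNS = ["sample_id", "site_id", "year", "tau1", "tau2", "mass_g"]
SITE_COLUMNS = ["site_id", "cluster", "lon", "lat", "alt"]


@dataclass(frozen=True)
class TrapSample:
    """One trap catch: site, year, inclusive exposure interval, wet mass.

    ``tau1``/``tau2`` are integer days-of-year (Jan 1 = 0), both inclusive;
    ``mass_g`` is wet biomass in grams.
    """

    sample_id: str
    site_id: str
    year: int
    tau1: int
    tau2: int
    mass_g: float

    def __post_init__(self) -> None:
        if self.tau2 < self.tau1:
            raise ValidationError(
                f"sample {self.sample_id}: tau2 ({self.tau2}) < tau1 ({self.tau1})"
            )
        if self.mass_g < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative mass {self.mass_g}"
            )

    @property
    def exposure_days(self) -> int:
        return self.tau2 - self.tau1 + 1


@dataclass(frozen=True)
class SiteRecord:
    """A trap location with its habitat cluster and coordinates."""

    site_id: str
    cluster: int
    lon: float
    lat: float
    alt: float

    def __post_init__(self) -> None:
        if self.cluster not in (1, 2, 3):
            raise ValidationError(
                f"site {self.site_id}: cluster must be 1, 2 or 3, got {self.cluster}"
            )
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValidationError(f"site {self.site_id}: non-finite coordinates")


@dataclass(frozen=True)
class DatasetSummary:
    n_samples: int
    n_sites: int
    n_site_years: int
    total_mass_g: float
    total_exposure_days: int
    mean_interval_days: float
    sd_interval_days: float


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SAMPLE_COLUMNS, "samples")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["tau1"] = df["tau1"].astype(int)
    df["tau2"] = df["tau2"].astype(int)
    df["mass_g"] = df["mass_g"].astype(float)
    bad = df.index[df["tau2"] < df["tau1"]]
    if len(bad):
        raise ValidationError(f"tau2 < tau1 at row index {bad[0]}")
    bad = df.index[df["mass_g"] < 0]
    if len(bad):
        raise ValidationError(f"negative mass at row index {bad[0]}")
    bad = df.index[(df["tau1"] < 0) | (df["tau2"] > 365)]
    if len(bad):
        raise ValidationError(f"exposure outside calendar year at row index {bad[0]}")
    dup = df.duplicated(subset=["site_id", "year", "tau1"])
    if dup.any():
        raise ValidationError(
            f"duplicate (site_id, year, tau1) at row index {df.index[dup][0]}"
        )
    return df


def read_samples(path) -> pd.DataFrame:
    """Read a trap-sample table (sample_id,site_id,year,tau1,tau2,mass_g)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str})
    return _validate_samples(df)


def write_samples(df: pd.DataFrame, path) -> None:
    _validate_samples(df)[SAMPLE_COLUMNS].to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, SITE_COLUMNS, "sites")
    df = df.copy()
    df["cluster"] = df["cluster"].astype(int)
    if not df["cluster"].isin([1, 2, 3]).all():
        raise ValidationError("cluster values must be in {1,2,3}")
    if df["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in sites table")
    return df


def write_sites(df: pd.DataFrame, path) -> None:
    _require_columns(df, SITE_COLUMNS, "sites")
    df[SITE_COLUMNS].to_csv(path, index=False)


def read_daily_covariates(path) -> pd.DataFrame:
    """Daily covariate table keyed by (site_id, year, day)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, ["site_id", "year", "day"], "daily covariates")
    return df


def read_siteyear_covariates(path) -> pd.DataFrame:
    """Site-year covariate table keyed by (site_id, year)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, ["site_id", "year"], "site-year covariates")
    return df


def read_draws(path) -> pd.DataFrame:
    """Posterior draws in long format (chain, iter, parameter, value)."""
    df = pd.read_csv(path)
    _require_columns(df, ["chain", "iter", "parameter", "value"], "draws")
    return df


def write_draws(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["chain", "iter", "parameter", "value"], "draws")
    df.to_csv(path, index=False)


def summarize(samples: pd.DataFrame) -> DatasetSummary:
    """Dataset-level totals: sample/site counts, exposure and interval moments.

    ``total_exposure_days`` sums the inclusive interval lengths
    ``tau2 - tau1 + 1``; the interval mean/sd are over the same lengths,
    matching the field convention of reporting the mean emptying interval.
    """
    if len(samples) == 0:
        raise ValidationError("cannot summarize an empty sample collection")
    samples = _validate_samples(samples)
    lengths = samples["tau2"] - samples["tau1"] + 1
    return DatasetSummary(
        n_samples=len(samples),
        n_sites=samples["site_id"].nunique(),
        n_site_years=len(samples[["site_id", "year"]].drop_duplicates()),
        total_mass_g=float(samples["mass_g"].sum()),
        total_exposure_days=int(lengths.sum()),
        mean_interval_days=float(lengths.mean()),
        sd_interval_days=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
    )
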