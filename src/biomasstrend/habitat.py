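"""Site-year habitat covariates: land-use interpolation, Ellenberg means,
plant-richness trends.

Land-use cover is measured at two survey epochs only; per-year values are
obtained by linear interpolation on the logit scale (equivalent to the
prediction of a saturated two-point binomial GLM with logit link).  Plant
community covariates come from survey tables: community-mean Ellenberg
indicator values, and Poisson mixed-model trends of species richness with a
random intercept per trap location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

#: effective number of pseudo-trials used to shrink exact 0/1 fractions
#: before the logit transform (keeps the transform finite, moves the value
#: by less than 1/2000).
N_EFF = 1000

ELLENBERG_INDICATORS = ["nitrogen", "ph", "light", "temperature", "moisture"]


def _shrink(p: float) -> float:
    eps = 1.0 / (2.0 * N_EFF)
    return float(np.clip(p, eps, 1.0 - eps))


def interpolate_cover(
    p1: float, y1: int, p2: float, y2: int, target_year: float
) -> float:
    """Logit-linear interpolation of a cover fraction between two epochs.

    Exactly reproduces ``p1`` at ``y1`` and ``p2`` at ``y2`` (up to the 0/1
    shrinkage); monotone in ``target_year`` whenever ``p1 != p2``.  Targets
    outside [y1, y2] are linearly extrapolated on the logit scale with a
    warning.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if y2 <= y1:
        raise ValueError("epoch years must satisfy y1 < y2")
    if not (y1 <= target_year <= y2):
        warnings.warn(
            f"target year {target_year} outside survey epochs [{y1}, {y2}]; "
            "extrapolating on the logit scale",
            stacklevel=2,
        )
    l1, l2 = logit(_shrink(p1)), logit(_shrink(p2))
    w = (target_year - y1) / (y2 - y1)
    return float(expit(l1 + w * (l2 - l1)))


def ellenberg_means(species: pd.DataFrame) -> pd.Series:
    """Community-mean Ellenberg indicator values over a species table.

    ``species`` has one row per species with indicator columns; species
    lacking a value for an indicator are skipped for that indicator.
    """
    cols = [c for c in species.columns if c in ELLENBERG_INDICATORS]
    if not cols:
        cols = [c for c in species.columns if c != "species"]
    sub = species[cols].apply(pd.to_numeric, errors="coerce")
    if sub.notna().sum().sum() == 0:
        raise ValueError("no species carries a value for any indicator")
    return sub.mean(skipna=True)


@dataclass
class RichnessTrend:
    slope: float
    se: float
    dispersion: float
    n_obs: int
    overdispersed: bool


def richness_trend(counts: pd.DataFrame, count_col: str = "richness") -> RichnessTrend:
    """Annual log-scale trend in species richness from site-year counts.

    Fits a Poisson log-link mixed model with a random intercept per site by
    Laplace-approximate (MAP) estimation, and reports the year slope with
    its standard error plus a residual-deviance/df dispersion diagnostic
    (values well above 1 indicate overdispersion; flagged above 1.5).
    """
    from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

    req = {"site_id", "year", count_col}
    missing = req - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing column(s): {sorted(missing)}")
    if counts["year"].nunique() < 2 or counts["site_id"].nunique() < 2:
        raise ValueError("need at least 2 years and 2 sites")
    y = counts[count_col].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("all counts are zero")

    year_c = counts["year"].to_numpy(dtype=float)
    year_c = year_c - year_c.mean()
    exog = np.column_stack([np.ones(len(y)), year_c])
    sites = pd.Categorical(counts["site_id"])
    Z = pd.get_dummies(sites).to_numpy(dtype=float)
    model = PoissonBayesMixedGLM(
        y, exog, exog_vc=Z, ident=np.zeros(Z.shape[1], dtype=int), vcp_p=3.0, fe_p=5.0
    )
    fit = model.fit_map()

    slope = float(fit.fe_mean[1])
    se = float(fit.fe_sd[1])
    eta = exog @ fit.fe_mean + Z @ fit.vc_mean
    mu = np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    deviance = 2.0 * float(np.sum(term - (y - mu)))
    df = max(len(y) - exog.shape[1] - Z.shape[1], 1)
    dispersion = deviance / df
    return RichnessTrend(
        slope=slope,
        se=se,
        dispersion=dispersion,
        n_obs=len(y),
        overdispersed=dispersion > 1.5,
    )
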