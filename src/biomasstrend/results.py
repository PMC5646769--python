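"""Posterior draws container, fit results, and MCMC diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws: values[chain, iteration, parameter]."""

    values: np.ndarray
    parameter_names: list[str]
    chains: int
    iterations: int
    burn_in: int
    thin: int
    seed: int

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be (chains, kept, parameters)")
        if self.values.shape[0] != self.chains:
            raise ValueError("chain count mismatch")
        if self.values.shape[2] != len(self.parameter_names):
            raise ValueError("parameter name count mismatch")

    @property
    def n_kept(self) -> int:
        return self.values.shape[1]

    def get(self, parameter: str) -> np.ndarray:
        """Per-chain draws of one parameter, shape (chains, kept)."""
        try:
            j = self.parameter_names.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}") from None
        return self.values[:, :, j]

    def flat(self, parameter: str) -> np.ndarray:
        return self.get(parameter).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format (chain, iter, parameter, value) for CSV round-trips."""
        ch, it, p = self.values.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(ch), it * p),
                "iter": np.tile(np.repeat(np.arange(it), p), ch),
                "parameter": np.tile(self.parameter_names, ch * it),
                "value": self.values.reshape(-1),
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, iterations: int = 0, burn_in: int = 0,
        thin: int = 1, seed: int = 0,
    ) -> "PosteriorDraws":
        names = list(dict.fromkeys(df["parameter"]))
        chains = df["chain"].nunique()
        wide = df.pivot_table(
            index=["chain", "iter"], columns="parameter", values="value", sort=False
        )[names]
        kept = len(wide) // chains
        values = wide.to_numpy().reshape(chains, kept, len(names))
        return cls(values, names, chains, iterations, burn_in, thin, seed)


def psrf(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Gelman-Rubin potential scale reduction factor R-hat.

    Classic (non-split) variant: with M chains of length N, within-chain
    variance W and between-chain variance B, R-hat = sqrt(((N-1)/N * W +
    B/N) / W).  Values near 1 indicate the chains are sampling the same
    distribution; the conventional convergence threshold here is 1.02.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with a PosteriorDraws input")
        x = draws.get(parameter)
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("psrf requires at least 2 chains")
    n = x.shape[1]
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def dic(deviance: np.ndarray, method: str = "var") -> tuple[float, float]:
    """Deviance Information Criterion and effective parameter count pD.

    ``method="var"`` (default) uses pD = var(D)/2, the convention of the
    R2jags toolchain; ``method="mean"`` uses pD = mean(D) - D(theta_bar),
    which requires the deviance evaluated at the posterior mean to be
    appended by the caller as ``deviance_at_mean``.
    Returns (DIC, pD) with DIC = mean(D) + pD.
    """
    d = np.asarray(deviance, dtype=float).reshape(-1)
    if d.size < 10:
        raise ValueError("need at least 10 deviance draws")
    if method != "var":
        raise ValueError("only the var(D)/2 convention is computed here; "
                         "use BiomassTrendResults.dic(method='mean') for the other")
    pd_ = float(d.var(ddof=1) / 2.0)
    return float(d.mean() + pd_), pd_


def empirical_pvalue(draws: np.ndarray | PosteriorDraws, parameter: str | None = None) -> float:
    """Two-sided empirical posterior p-value: 2 * min(P(>0), P(<0)), capped at 1.

    Draws exactly equal to zero count to neither side.  An all-one-sided
    posterior returns 0.0 (interpretable as < 1/n_draws).
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with a PosteriorDraws input")
        x = draws.flat(parameter)
    else:
        x = np.asarray(draws, dtype=float).reshape(-1)
    if x.size < 100:
        raise ValueError("need at least 100 draws for an empirical p-value")
    p = 2.0 * min(np.mean(x > 0), np.mean(x < 0))
    return float(min(p, 1.0))


class BiomassTrendResults:
    """Posterior summaries, diagnostics and projections for a fitted model.

    Attributes
    ----------
    model : BiomassTrendModel
    draws : PosteriorDraws
    """

    def __init__(self, model, draws: PosteriorDraws, accept_rates=None):
        self.model = model
        self.draws = draws
        self.accept_rates = accept_rates or []

    # -- point estimates ----------------------------------------------------
    @property
    def parameter_names(self) -> list[str]:
        return [p for p in self.draws.parameter_names if p != "deviance"]

    def posterior_mean(self, parameter: str) -> float:
        return float(self.draws.flat(parameter).mean())

    def posterior_sd(self, parameter: str) -> float:
        return float(self.draws.flat(parameter).std(ddof=1))

    def credible_interval(self, parameter: str, level: float = 0.95):
        x = self.draws.flat(parameter)
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(x, [lo, 1.0 - lo]))

    def params_at_posterior_mean(self):
        """ModelParams assembled from componentwise posterior means."""
        from .model import ModelParams

        d = self.model.design
        beta = np.array([self.posterior_mean(c) for c in d.columns])
        u = np.array([self.posterior_mean(f"u[{s}]") for s in d.site_ids])
        return ModelParams(
            c=self.posterior_mean("c"),
            log_lambda=(
                self.posterior_mean("log_lambda")
                if self.model.spec.include_year
                else 0.0
            ),
            beta=beta,
            u=u,
            sigma2_site=self.posterior_mean("sigma_site") ** 2,
            v=self.posterior_mean("v"),
        )

    # -- diagnostics ----------------------------------------------------------
    def psrf(self, parameter: str) -> float:
        return psrf(self.draws, parameter)

    def psrf_all(self) -> pd.Series:
        return pd.Series(
            {p: self.psrf(p) for p in self.parameter_names}, name="rhat"
        )

    def max_psrf(self) -> float:
        return float(self.psrf_all().max())

    def dic(self, method: str = "var") -> tuple[float, float]:
        d = self.draws.flat("deviance")
        if method == "var":
            return dic(d)
        if method == "mean":
            dev_at_mean = -2.0 * self.model.log_likelihood(
                self.params_at_posterior_mean()
            )
            pd_ = float(d.mean() - dev_at_mean)
            return float(d.mean() + pd_), pd_
        raise ValueError("method must be 'var' or 'mean'")

    def r2(self) -> float:
        """Squared correlation of observed vs posterior-mean log biomass.

        Computed over samples with positive observed mass (log of a clipped
        zero catch is undefined).
        """
        from .model import aggregate_moments

        mu, _ = aggregate_moments(self.model.design, self.params_at_posterior_mean())
        m = self.model.mass_g
        ok = m > 0
        r = np.corrcoef(np.log(m[ok]), np.log(mu[ok]))[0, 1]
        return float(r * r)

    def empirical_pvalue(self, parameter: str) -> float:
        return empirical_pvalue(self.draws, parameter)

    def diagnostics_report(self) -> dict:
        dic_, pd_ = self.dic()
        return {
            "rhat": self.psrf_all().to_dict(),
            "max_rhat": self.max_psrf(),
            "dic": dic_,
            "pd": pd_,
            "r2": self.r2(),
            "accept_rates": self.accept_rates,
            "seed": self.draws.seed,
            "protocol": {
                "chains": self.draws.chains,
                "iterations": self.draws.iterations,
                "burn_in": self.draws.burn_in,
                "thin": self.draws.thin,
            },
        }

    # -- projections (delegated) ---------------------------------------------
    def project_season(self, year, window=(90, 302), **kwargs):
        from . import projections

        return projections.project_season(self, year, window=window, **kwargs)

    def weighted_decline(self, year_from, year_to, window=(90, 302), **kwargs):
        from . import projections

        return projections.weighted_decline(
            self, year_from, year_to, window=window, **kwargs
        )

    def peak_decline(self, year_from, year_to, window=(90, 302), **kwargs):
        from . import projections

        return projections.peak_decline(
            self, year_from, year_to, window=window, **kwargs
        )

    # -- display ---------------------------------------------------------------
    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd, credible bounds and empirical P per parameter.

        Site random effects are collapsed out of the table; variance
        components carry no P-value (they are constrained positive).
        """
        rows = []
        for p in self.parameter_names:
            if p.startswith("u["):
                continue
            lo, hi = self.credible_interval(p, level)
            is_var = p in ("sigma_site", "v")
            rows.append(
                {
                    "parameter": p,
                    "mean": self.posterior_mean(p),
                    "sd": self.posterior_sd(p),
                    f"{100 * (1 - level) / 2:.1f}%": lo,
                    f"{100 * (1 + level) / 2:.1f}%": hi,
                    "P": np.nan if is_var else self.empirical_pvalue(p),
                    "rhat": self.psrf(p),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self) -> str:
        return (
            f"<BiomassTrendResults spec={self.model.spec.name!r} "
            f"chains={self.draws.chains} kept={self.draws.n_kept} "
            f"max_rhat={self.max_psrf():.3f}>"
        )
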