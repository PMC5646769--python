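"""Adaptive Metropolis-within-Gibbs sampler for the biomass trend model.

Sampling strategy
-----------------
Scalar random-walk blocks for the intercept, every regression direction,
every site effect and sqrt(v); an exact Gibbs draw for sigma_site (its full
conditional under a Uniform(0, 10) prior on the standard deviation is a
truncated gamma in the precision); and a translation sweep that moves mass
between the intercept and the mean of the site effects without changing the
linear predictor.  Proposal scales adapt toward a 0.44 acceptance rate
during burn-in only, so the post-burn-in kernel satisfies detailed balance.

Parameterisation.  The design columns (year index included) are centered
and orthogonalised internally by a group-wise QR factorisation — one group
for columns constant within every sample (year, cluster dummies, site-year
covariates and their year interactions), one for day-varying columns (day,
day^2, daily weather, year x day products).  Random-walk moves are made on
the orthogonal coordinates, which decorrelates e.g. the day and year x day
directions, and are mapped back exactly to the model-scale coefficients for
the prior evaluation and for recording, so the posterior sampled is exactly
the one on the original parameterisation.  Columns with zero variance
(e.g. a cluster dummy with no sites in that cluster) carry no likelihood
information; their coefficients are drawn i.i.d. from the prior, which is
the exact full conditional.

Bookkeeping exploits the model structure: the likelihood depends on the
day-level predictor only through the per-sample sums S1 = sum exp(eta) and
S2 = sum exp(2 eta).  A proposal that shifts eta along a direction constant
within every sample rescales S1 and S2 by per-sample factors and never
touches the day grid.
"""

from __future__ import annotations

import numpy as np

from .model import BiomassTrendModel
from .results import BiomassTrendResults, PosteriorDraws

_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 50
_PRIOR_SD = 1e3  # "flat normal" prior sd on location parameters
_SIGMA_UPPER = 10.0  # Uniform(0, 10) on sigma_site and sqrt(v)

_LOG2PI = float(np.log(2.0 * np.pi))


def _a_of_v(v: float) -> float:
    # sigma2_j = a(v) * S2_j with a(v) = e^v (e^v - 1)
    return float(np.exp(v) * np.expm1(v))


def _ll_vec(S1, S2, a, m):
    s2 = a * S2
    return -0.5 * (_LOG2PI + np.log(s2) + (m - S1) ** 2 / s2)


class _ChainState:
    """Mutable state of one chain, with incremental likelihood updates."""

    def __init__(self, model: BiomassTrendModel, rng: np.random.Generator):
        self.rng = rng
        d = model.design
        self.m = model.mass_g
        self.J = d.n_samples
        self.n_sites = len(d.site_ids)
        self.include_year = bool(model.spec.include_year)

        self.starts = d.sample_starts
        self.site_of_sample = d.sample_site
        self.site_of_day = d.site_index
        bounds = np.searchsorted(self.site_of_sample, np.arange(self.n_sites + 1))
        self.site_slices = [
            slice(bounds[s], bounds[s + 1]) for s in range(self.n_sites)
        ]

        # --- internal orthogonal parameterisation -------------------------
        V_cols = ([d.year_k] if self.include_year else []) + [
            d.X[:, j] for j in range(d.X.shape[1])
        ]
        self.q_total = len(V_cols)
        D = d.n_days
        self.col_means = np.array([c.mean() for c in V_cols])
        Vc = np.column_stack(V_cols) - self.col_means if V_cols else np.zeros((D, 0))

        sd = Vc.std(axis=0) if self.q_total else np.array([])
        self.active = np.where(sd > 1e-12)[0]
        self.degenerate = np.where(sd <= 1e-12)[0]

        # split active columns into sample-constant and day-varying groups
        mins, maxs = np.minimum.reduceat, np.maximum.reduceat
        const_group, vary_group = [], []
        for j in self.active:
            lo, hi = mins(Vc[:, j], self.starts), maxs(Vc[:, j], self.starts)
            (const_group if np.allclose(lo, hi, atol=1e-12) else vary_group).append(j)
        self.order = const_group + vary_group  # internal column order
        self.qB = len(const_group)
        self.q = len(self.order)

        # per-group QR with scaling to ~unit-variance columns
        def qr_scaled(cols):
            if not cols:
                return np.zeros((D, 0)), np.zeros((0, 0))
            W = Vc[:, cols]
            Q, R = np.linalg.qr(W, mode="reduced")
            if np.any(np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(R).max())):
                raise ValueError(
                    "design columns are collinear; remove redundant covariates"
                )
            s = np.sqrt(D)
            return Q * s, R / s  # W = (Q s)(R / s)

        QB, RB = qr_scaled(const_group)
        QA, RA = qr_scaled(vary_group)
        self.Q = np.hstack([QB, QA]) if self.q else np.zeros((D, 0))
        # phi_internal = blockdiag(RB, RA) maps gamma -> coefficients in
        # self.order; dphi[:, j] is the coefficient move per unit gamma_j
        self.dphi = np.zeros((self.q, self.q))
        if self.qB:
            self.dphi[: self.qB, : self.qB] = np.linalg.inv(RB)
        if self.q - self.qB:
            self.dphi[self.qB:, self.qB:] = np.linalg.inv(RA)
        # per-sample value of each sample-constant orthogonal column
        self.w_const = (
            mins(self.Q[:, : self.qB], self.starts) if self.qB else np.zeros((self.J, 0))
        )

        # translation sweeps for site-constant design columns: moving the
        # coefficient by delta while shifting the site effects by
        # -delta * x_s (and the intercept by delta * mean(x)) leaves the
        # linear predictor invariant, decorrelating e.g. a cluster dummy
        # from the site effects of that cluster
        day_bounds = np.searchsorted(self.site_of_day, np.arange(self.n_sites + 1))
        self.col_sweeps = []
        for pos, j in enumerate(self.order):
            raw_col = Vc[:, j] + self.col_means[j]
            lo = np.array(
                [raw_col[day_bounds[s]:day_bounds[s + 1]].min()
                 if day_bounds[s] < day_bounds[s + 1] else 0.0
                 for s in range(self.n_sites)]
            )
            hi = np.array(
                [raw_col[day_bounds[s]:day_bounds[s + 1]].max()
                 if day_bounds[s] < day_bounds[s + 1] else 0.0
                 for s in range(self.n_sites)]
            )
            if np.allclose(lo, hi, atol=1e-12) and np.any(lo != 0.0):
                e = np.zeros(self.q)
                e[pos] = 1.0
                gvec = np.linalg.solve(self.dphi, e)
                self.col_sweeps.append(
                    {"phi_index": j, "gvec": gvec, "x_site": lo,
                     "x_mean": float(self.col_means[j]),
                     "key": f"sweep_col{j}"}
                )

        # --- dispersed initial values -------------------------------------
        mean_daily = model.mass_g.sum() / (
            model.samples["tau2"] - model.samples["tau1"] + 1
        ).sum()
        self.c = float(np.log(max(mean_daily, 1e-6)) + rng.normal(0, 0.3))
        self.gamma = rng.normal(0, 0.05, size=self.q)
        self.phi = np.zeros(self.q_total)
        if self.q:
            self.phi[self.order] = self.dphi @ self.gamma
        self.phi[self.degenerate] = rng.normal(0, 1.0, size=len(self.degenerate))
        self.u = rng.normal(0, 0.05, size=self.n_sites)
        self.sigma_site = float(rng.uniform(0.2, 0.6))
        self.sqrt_v = float(np.sqrt(0.5) * np.exp(rng.normal(0, 0.2)))

        self._recompute()

        self.scales = {"c": np.log(0.05), "v": np.log(0.03), "sweep": np.log(0.1)}
        for j in range(self.q):
            self.scales[f"g{j}"] = np.log(0.02)
        for sw in self.col_sweeps:
            self.scales[sw["key"]] = np.log(0.1)
        self.u_scales = np.full(self.n_sites, np.log(0.1))
        self.acc = {k: [0, 0] for k in self.scales}
        self.u_acc = np.zeros((self.n_sites, 2), dtype=int)

    # -- full recomputation -------------------------------------------------
    def _eta(self) -> np.ndarray:
        eta = self.c + self.u[self.site_of_day]
        if self.q:
            eta = eta + self.Q @ self.gamma
        return eta

    def _recompute(self) -> None:
        self.ez = np.exp(self._eta())
        self.S1 = np.add.reduceat(self.ez, self.starts)
        self.S2 = np.add.reduceat(self.ez * self.ez, self.starts)
        self.a = _a_of_v(self.sqrt_v**2)
        self.ll_terms = _ll_vec(self.S1, self.S2, self.a, self.m)
        self.ll = float(self.ll_terms.sum())

    def _refresh_ez(self) -> None:
        self.ez = np.exp(self._eta())

    # -- MH helpers ----------------------------------------------------------
    def _try_sample_constant(self, w_sample, delta: float, lp_diff: float) -> bool:
        f = np.exp(delta * w_sample)
        S1n = self.S1 * f
        S2n = self.S2 * f * f
        lln = _ll_vec(S1n, S2n, self.a, self.m)
        if np.log(self.rng.uniform()) < lln.sum() - self.ll + lp_diff:
            self.S1, self.S2 = S1n, S2n
            self.ez = None  # refreshed lazily before the next day-level move
            self.ll_terms = lln
            self.ll = float(lln.sum())
            return True
        return False

    def _try_day_level(self, w_day, delta: float, lp_diff: float) -> bool:
        if self.ez is None:
            self._refresh_ez()
        ezn = self.ez * np.exp(delta * w_day)
        S1n = np.add.reduceat(ezn, self.starts)
        S2n = np.add.reduceat(ezn * ezn, self.starts)
        lln = _ll_vec(S1n, S2n, self.a, self.m)
        if np.log(self.rng.uniform()) < lln.sum() - self.ll + lp_diff:
            self.ez, self.S1, self.S2 = ezn, S1n, S2n
            self.ll_terms = lln
            self.ll = float(lln.sum())
            return True
        return False

    @staticmethod
    def _normal_lp(x, sd: float = _PRIOR_SD) -> float:
        return float(-0.5 * np.sum(np.square(x)) / (sd * sd))

    # -- one Gibbs scan -------------------------------------------------------
    def step(self, adapt: bool) -> None:
        rng = self.rng

        # intercept (sample-constant with w = 1)
        delta = rng.normal(0, np.exp(self.scales["c"]))
        lp = self._normal_lp(self.c + delta) - self._normal_lp(self.c)
        ok = self._try_sample_constant(np.ones(self.J), delta, lp)
        if ok:
            self.c += delta
        self._tally("c", ok)

        # orthogonal regression directions
        for j in range(self.q):
            key = f"g{j}"
            delta = rng.normal(0, np.exp(self.scales[key]))
            dmove = self.dphi[:, j] * delta
            cols = np.nonzero(dmove)[0]
            phi_old = self.phi[[self.order[i] for i in cols]]
            lp = self._normal_lp(phi_old + dmove[cols]) - self._normal_lp(phi_old)
            if j < self.qB:
                ok = self._try_sample_constant(self.w_const[:, j], delta, lp)
            else:
                ok = self._try_day_level(self.Q[:, j], delta, lp)
            if ok:
                self.gamma[j] += delta
                for i in cols:
                    self.phi[self.order[i]] += dmove[i]
            self._tally(key, ok)

        # unidentified columns: exact conditional = prior
        if len(self.degenerate):
            self.phi[self.degenerate] = rng.normal(
                0, _PRIOR_SD, size=len(self.degenerate)
            )

        # site random effects (local likelihood only)
        s2u = self.sigma_site**2
        for s in range(self.n_sites):
            sl = self.site_slices[s]
            if sl.start == sl.stop:
                self.u[s] = rng.normal(0, self.sigma_site)
                continue
            delta = rng.normal(0, np.exp(self.u_scales[s]))
            un = self.u[s] + delta
            f = np.exp(delta)
            S1n = self.S1[sl] * f
            S2n = self.S2[sl] * f * f
            lln = _ll_vec(S1n, S2n, self.a, self.m[sl])
            dlp = -0.5 * (un * un - self.u[s] ** 2) / s2u
            dll = lln.sum() - self.ll_terms[sl].sum()
            ok = np.log(rng.uniform()) < dll + dlp
            if ok:
                self.u[s] = un
                self.S1[sl], self.S2[sl] = S1n, S2n
                self.ll_terms[sl] = lln
                self.ll += float(dll)
                self.ez = None
            self.u_acc[s, 1] += 1
            self.u_acc[s, 0] += int(ok)

        # translation sweep: c -> c + d, u -> u - d (predictor invariant)
        delta = rng.normal(0, np.exp(self.scales["sweep"]))
        dlp = (
            -0.5 * float(np.sum((self.u - delta) ** 2 - self.u**2)) / s2u
            + self._normal_lp(self.c + delta)
            - self._normal_lp(self.c)
        )
        ok = np.log(rng.uniform()) < dlp
        if ok:
            self.c += delta
            self.u -= delta
            self.ez = None
        self._tally("sweep", ok)

        # per-column translation sweeps (predictor invariant)
        for sw in self.col_sweeps:
            delta = rng.normal(0, np.exp(self.scales[sw["key"]]))
            j = sw["phi_index"]
            un = self.u - delta * sw["x_site"]
            cn = self.c + delta * sw["x_mean"]
            dlp = (
                -0.5 * float(np.sum(un**2 - self.u**2)) / s2u
                + self._normal_lp(self.phi[j] + delta)
                - self._normal_lp(self.phi[j])
                + self._normal_lp(cn)
                - self._normal_lp(self.c)
            )
            ok = np.log(rng.uniform()) < dlp
            if ok:
                self.u = un
                self.c = cn
                self.phi[j] += delta
                self.gamma += delta * sw["gvec"]
            self._tally(sw["key"], ok)

        # sigma_site: exact Gibbs (truncated gamma in the precision)
        A = 0.5 * float(np.sum(self.u**2))
        shape = 0.5 * (self.n_sites - 1)
        if A > 0 and shape > 0:
            for _ in range(100):
                tau = rng.gamma(shape, 1.0 / A)
                if tau > 1.0 / _SIGMA_UPPER**2:
                    self.sigma_site = float(1.0 / np.sqrt(tau))
                    break

        # residual log-variance v via its standard deviation sqrt(v)
        delta = rng.normal(0, np.exp(self.scales["v"]))
        sn = self.sqrt_v + delta
        ok = False
        if 0.0 < sn < _SIGMA_UPPER:
            an = _a_of_v(sn * sn)
            lln = _ll_vec(self.S1, self.S2, an, self.m)
            if np.log(rng.uniform()) < lln.sum() - self.ll:
                ok = True
                self.sqrt_v = sn
                self.a = an
                self.ll_terms = lln
                self.ll = float(lln.sum())
        self._tally("v", ok)

        if adapt:
            self._adapt()

    def _tally(self, key: str, ok: bool) -> None:
        self.acc[key][1] += 1
        self.acc[key][0] += int(ok)

    def _adapt(self) -> None:
        for key, (n_ok, n) in self.acc.items():
            if n >= _ADAPT_BATCH:
                step = min(0.25, 2.0 / np.sqrt(max(n, 1)))
                self.scales[key] += step if n_ok / n > _TARGET_ACCEPT else -step
                self.acc[key] = [0, 0]
        mask = self.u_acc[:, 1] >= _ADAPT_BATCH
        if mask.any():
            rate = self.u_acc[mask, 0] / self.u_acc[mask, 1]
            self.u_scales[mask] += np.where(rate > _TARGET_ACCEPT, 0.25, -0.25)
            self.u_acc[mask] = 0

    # -- reporting -------------------------------------------------------------
    @property
    def c_reported(self) -> float:
        # undo the internal centering of the design columns
        return float(self.c - self.col_means @ self.phi)

    def reported_coefficients(self) -> np.ndarray:
        """(log_lambda if present, then beta) on the model scale."""
        return self.phi.copy()

    @property
    def deviance(self) -> float:
        return -2.0 * self.ll


def run_chains(
    model: BiomassTrendModel,
    seed: int,
    chains: int = 3,
    iterations: int = 6000,
    burn_in: int = 1000,
    thin: int = 5,
    progress: bool = False,
) -> BiomassTrendResults:
    """Run independent chains and collect thinned post-burn-in draws."""
    if seed is None:
        raise ValueError("an explicit seed is required")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    d = model.design
    param_names = (
        ["c"]
        + (["log_lambda"] if model.spec.include_year else [])
        + list(d.columns)
        + [f"u[{s}]" for s in d.site_ids]
        + ["sigma_site", "v", "deviance"]
    )
    kept = (iterations - burn_in) // thin
    out = np.empty((chains, kept, len(param_names)))
    accept_rates = []

    root = np.random.SeedSequence(seed)
    for ch, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        state = _ChainState(model, rng)
        row = 0
        for it in range(iterations):
            state.step(adapt=it < burn_in)
            if it >= burn_in and (it - burn_in) % thin == 0 and row < kept:
                vals = np.concatenate(
                    [
                        [state.c_reported],
                        state.reported_coefficients(),
                        state.u,
                        [state.sigma_site, state.sqrt_v**2, state.deviance],
                    ]
                )
                out[ch, row] = vals
                row += 1
            if progress and (it + 1) % 1000 == 0:
                print(f"chain {ch + 1}: {it + 1}/{iterations}", flush=True)
        accept_rates.append(
            {k: (a[0] / a[1] if a[1] else np.nan) for k, a in state.acc.items()}
        )

    draws = PosteriorDraws(
        values=out,
        parameter_names=param_names,
        chains=chains,
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
    )
    return BiomassTrendResults(model, draws, accept_rates=accept_rates)
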